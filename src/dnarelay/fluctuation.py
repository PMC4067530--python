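"""Chromosomal-locus elasticity and derived biophysical quantities.

A DNA locus tethered by the chromosome behaves as a particle in a harmonic
well: the probability of a deviation dx from its equilibrium is the
Boltzmann factor exp(-k_sp dx^2 / 2 kT), i.e. a zero-mean Gaussian with
1/sigma^2 = k_sp/kT.  Pooled per-trajectory deviations therefore yield the
effective spring constants of the chromosome, and simple mobility arguments
turn those into forces and the optimal ParA ATP-hydrolysis time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy

__all__ = [
    "FluctuationFit",
    "SpringConstants",
    "ForceEstimate",
    "FilamentBounds",
    "pool_deviations",
    "fit_asymmetric_gaussian",
    "sigma_to_kspring",
    "drag_force",
    "elastic_force",
    "optimal_hydrolysis_time",
    "effective_D_at_timescale",
    "filament_length_bounds",
]

log = logging.getLogger(__name__)


@dataclass
class FluctuationFit:
    sigma_long: float          # um
    sigma_long_err: float
    sigma_short: float         # um
    sigma_short_err: float
    n_points: int
    method: str = "ml"


@dataclass
class SpringConstants:
    k_long: float              # pN/nm
    k_short: float             # pN/nm
    k_over_kT_long: float      # um^-2, exactly 1/sigma_long^2
    k_over_kT_short: float     # um^-2
    temperature: float         # K


@dataclass
class ForceEstimate:
    value: float               # pN
    formula: str               # "drag" | "elastic"
    inputs: dict


@dataclass
class FilamentBounds:
    nucleoprotein_nm: float
    linear_nm: float


# ---------------------------------------------------------------------------


def pool_deviations(trajectories, min_frames: int = 5):
    """Pool per-trajectory mean-subtracted deviations across cells.

    ``trajectories`` is an iterable of (x, y) arrays (um), one per cell.
    Each trajectory's own mean is removed per axis, which cancels
    cell-to-cell variability in equilibrium position; trajectories shorter
    than ``min_frames`` are excluded (logged).
    Returns pooled (dx, dy) arrays.
    """
    dxs, dys = [], []
    n_excluded = 0
    for x, y in trajectories:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < min_frames:
            n_excluded += 1
            continue
        dxs.append(x - x.mean())
        dys.append(y - y.mean())
    if n_excluded:
        log.info("pool_deviations: excluded %d trajectories shorter than %d frames",
                 n_excluded, min_frames)
    if not dxs:
        raise ValueError("no trajectory met the minimum length")
    return np.concatenate(dxs), np.concatenate(dys)


def _fit_sigma_ml(d: np.ndarray) -> tuple[float, float]:
    sigma = math.sqrt(float(np.mean(d**2)))
    return sigma, sigma / math.sqrt(2.0 * len(d))


def _fit_sigma_binned(d: np.ndarray, bins: int = 41) -> tuple[float, float]:
    """Least-squares fit of a zero-mean Gaussian to the binned density."""
    density, edges = np.histogram(d, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, sigma):
        return a * np.exp(-(x**2) / (2.0 * sigma**2))

    s0 = float(np.std(d))
    popt, pcov = curve_fit(gauss, centers, density, p0=(density.max(), s0))
    return abs(float(popt[1])), float(np.sqrt(pcov[1, 1]))


def fit_asymmetric_gaussian(dx, dy, method: str = "ml", min_points: int = 100) -> FluctuationFit:
    """Fit independent zero-mean Gaussians per axis (2-D asymmetric Gaussian).

    The 2-D well factorises along the cell axes, so sigma_long and
    sigma_short are fitted separately.  ``method='ml'`` uses the
    closed-form maximum-likelihood sigma (the RMS deviation); ``'binned'``
    performs a least-squares fit to the binned density (the two differ only
    in their error estimates for well-behaved data).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if not (np.isfinite(dx).all() and np.isfinite(dy).all()):
        raise ValueError("deviations must be finite")
    if len(dx) < min_points or len(dy) < min_points:
        raise ValueError(f"need at least {min_points} pooled deviations")
    fitter = {"ml": _fit_sigma_ml, "binned": _fit_sigma_binned}[method]
    sl, sle = fitter(dx)
    ss, sse = fitter(dy)
    return FluctuationFit(sigma_long=sl, sigma_long_err=sle,
                          sigma_short=ss, sigma_short_err=sse,
                          n_points=len(dx), method=method)


def sigma_to_kspring(sigma_long: float, sigma_short: float | None = None,
                     temperature: float = DEFAULT_TEMPERATURE_K) -> SpringConstants:
    """Convert fluctuation SDs (um) to spring constants via k_sp/kT = 1/sigma^2.

    k (pN/nm) = kT / sigma^2 with kT in pN*um and sigma in um gives pN/um;
    divided by 1000 for pN/nm.  When only one sigma is given the short-axis
    fields repeat the long-axis ones.
    """
    if sigma_short is None:
        sigma_short = sigma_long
    if sigma_long <= 0 or sigma_short <= 0:
        raise ValueError("sigma must be positive")
    kT = thermal_energy(temperature)
    return SpringConstants(
        k_long=kT / sigma_long**2 / 1000.0,
        k_short=kT / sigma_short**2 / 1000.0,
        k_over_kT_long=1.0 / sigma_long**2,
        k_over_kT_short=1.0 / sigma_short**2,
        temperature=temperature,
    )


def drag_force(v: float, D: float, temperature: float = DEFAULT_TEMPERATURE_K) -> ForceEstimate:
    """Stokes-drag force required to move at speed ``v`` (um/s): F = v kT / D."""
    if v < 0 or D <= 0:
        raise ValueError("need v >= 0 and D > 0")
    value = v * thermal_energy(temperature) / D
    return ForceEstimate(value=value, formula="drag",
                         inputs={"v_um_s": v, "D_um2_s": D, "temperature_K": temperature})


def elastic_force(k_sp: float, sigma_nm: float) -> ForceEstimate:
    """Characteristic elastic force of a stretched tether: F = k_sp * sigma.

    ``k_sp`` in pN/nm, ``sigma`` in nm, result in pN.
    """
    if k_sp < 0 or sigma_nm < 0:
        raise ValueError("inputs must be non-negative")
    return ForceEstimate(value=k_sp * sigma_nm, formula="elastic",
                         inputs={"k_sp_pN_nm": k_sp, "sigma_nm": sigma_nm})


def optimal_hydrolysis_time(sigma_long: float, D_PC: float) -> tuple[float, float]:
    """Optimal tether attachment time and hydrolysis rate.

    The complex relaxes toward a tether anchor on the time scale
    dt = kT/(D_PC k_sp) = sigma_long^2 / D_PC; holding on longer wastes
    time, releasing earlier under-uses the elastic stroke.  Returns
    (dt in s, rate = 1/dt in 1/s).
    """
    if sigma_long <= 0 or D_PC <= 0:
        raise ValueError("inputs must be positive")
    dt = sigma_long**2 / D_PC
    return dt, 1.0 / dt


def effective_D_at_timescale(D_app: float, alpha: float, dt: float) -> float:
    """Effective diffusivity of subdiffusive loci at time scale ``dt``.

    For generalized diffusion MSD ~ D_app t^alpha, the instantaneous
    diffusivity at scale dt is D = D_app dt^(alpha - 1) (alpha = 1 returns
    D_app, normal diffusion).
    """
    if D_app <= 0 or dt <= 0 or not 0 < alpha <= 1:
        raise ValueError("need D_app > 0, dt > 0 and 0 < alpha <= 1")
    return D_app * dt ** (alpha - 1.0)


def filament_length_bounds(
    n_dimers: int,
    dimers_per_pitch: float = 4.4,
    pitch_nm: float = 12.0,
    dimer_length_nm: float = 6.4,
) -> FilamentBounds:
    """Upper bounds on a hypothetical ParA filament from the cellular count.

    Nucleoprotein-helix bound: n / (dimers per helical pitch) * pitch.
    Linear bound: dimers stacked back-to-back along their longest dimension.
    """
    if n_dimers < 0:
        raise ValueError("n_dimers must be >= 0")
    return FilamentBounds(
        nucleoprotein_nm=n_dimers / dimers_per_pitch * pitch_nm,
        linear_nm=n_dimers * dimer_length_nm,
    )
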