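"""NADH-coupled ATPase assay reduction and substrate-dependence fits.

In the coupled assay, each ADP produced oxidizes one NADH, so the A340
decline rate is proportional to the ATP-turnover rate.  Time courses are
reduced to initial velocities by linear regression, converted to ADP
production rates (uM/hr) via an NADH standard curve, normalised by enzyme
concentration into specific activities (1/hr), and fitted with the
Michaelis-Menten equation v = Vmax S / (K + S) or a proportional law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VelocityFit",
    "SpecificActivity",
    "MMFitResult",
    "LinearRateFit",
    "initial_velocity",
    "convert_to_rate",
    "specific_activity",
    "fit_michaelis_menten",
    "fit_linear_rate",
    "HR_PER_S",
]

#: 1 hr^-1 in s^-1.
HR_PER_S = 1.0 / 3600.0

#: Assay detection baseline for specific activity, 1/hr.
ACTIVITY_BASELINE_PER_HR = 0.5


@dataclass
class VelocityFit:
    slope: float               # absorbance/min
    stderr: float
    n_points: int
    flagged: bool = False      # positive-drift artifact


@dataclass
class SpecificActivity:
    value: float               # 1/hr
    below_baseline: bool
    baseline: float = ACTIVITY_BASELINE_PER_HR

    def __str__(self) -> str:
        return f"<{self.baseline} hr^-1" if self.below_baseline else f"{self.value:g} hr^-1"


@dataclass
class MMFitResult:
    vmax: float                # specific-activity convention: k_cat, 1/hr
    K: float                   # substrate units (mg/ml DNA, uM ATP/ParB)
    vmax_err: float
    K_err: float
    converged: bool

    @property
    def k_cat_per_s(self) -> float:
        return self.vmax * HR_PER_S


@dataclass
class LinearRateFit:
    k_cat: float               # 1/hr, slope of rate vs [enzyme]
    stderr: float
    intercept: float           # 0 for through-origin fits
    through_origin: bool


def initial_velocity(
    t_min: np.ndarray,
    a340: np.ndarray,
    window: tuple[float, float] | None = None,
    control_slope: float = 0.0,
    drift_tolerance: float = 0.0,
) -> VelocityFit:
    """OLS slope of an A340 time course over the initial window.

    ``window`` is (t_lo, t_hi) in minutes (default: the whole course);
    ``control_slope`` is the matched no-enzyme control slope, subtracted to
    correct for spontaneous ATP hydrolysis and NADH oxidation.  A corrected
    slope more positive than ``drift_tolerance`` (A340 rising) is flagged
    as an artifact.
    """
    t = np.asarray(t_min, dtype=float)
    a = np.asarray(a340, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, a = t[keep], a[keep]
    if len(t) < 4:
        raise ValueError("need at least 4 points in the regression window")
    fit = stats.linregress(t, a)
    slope = float(fit.slope) - control_slope
    return VelocityFit(
        slope=slope,
        stderr=float(fit.stderr),
        n_points=len(t),
        flagged=slope > drift_tolerance,
    )


def convert_to_rate(slope_abs_per_min: float, nadh_standard_uM_per_abs: float) -> float:
    """Convert an A340 slope to an ADP production rate in uM/hr.

    The NADH standard curve gives uM of NADH per absorbance unit; A340
    declines as NADH is oxidized, so a negative slope maps to a positive
    rate.
    """
    if nadh_standard_uM_per_abs <= 0:
        raise ValueError("standard-curve slope must be positive")
    return -slope_abs_per_min * nadh_standard_uM_per_abs * 60.0


def specific_activity(rate_uM_per_hr: float, parA_uM: float,
                      baseline: float = ACTIVITY_BASELINE_PER_HR) -> SpecificActivity:
    """ADP production rate divided by enzyme concentration, in 1/hr.

    Activities below the assay baseline are reported as a "< baseline"
    sentinel rather than a numeric estimate.
    """
    if parA_uM == 0:
        raise ZeroDivisionError("specific activity undefined at [ParA] = 0")
    value = rate_uM_per_hr / parA_uM
    return SpecificActivity(value=value, below_baseline=value < baseline, baseline=baseline)


def michaelis_menten(S, vmax, K):
    S = np.asarray(S, dtype=float)
    return vmax * S / (K + S)


def fit_michaelis_menten(S, v) -> MMFitResult:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialization Vmax0 = max(v), K0 = median(S); asymptotic standard
    errors from the covariance of the fit.  Non-convergence returns a
    result with ``converged=False`` and NaN parameters.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if np.any(v < 0):
        raise ValueError("velocities must be non-negative")
    p0 = (float(v.max()), float(np.median(S[S > 0])) if np.any(S > 0) else 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, S, v, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        errs = np.sqrt(np.diag(pcov))
    except (RuntimeError, ValueError):
        return MMFitResult(vmax=math.nan, K=math.nan, vmax_err=math.nan,
                           K_err=math.nan, converged=False)
    return MMFitResult(vmax=float(popt[0]), K=float(popt[1]),
                       vmax_err=float(errs[0]), K_err=float(errs[1]), converged=True)


def fit_linear_rate(conc_uM, rates_uM_per_hr, through_origin: bool = True) -> LinearRateFit:
    """Slope of ADP production rate vs enzyme concentration (k_cat in 1/hr).

    Through-origin by default (rate = k_cat [ParA]); a free intercept is
    available for checking the proportionality assumption.
    """
    x = np.asarray(conc_uM, dtype=float)
    y = np.asarray(rates_uM_per_hr, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if through_origin:
        sxx = float(np.sum(x * x))
        if sxx == 0:
            return LinearRateFit(k_cat=0.0, stderr=math.nan, intercept=0.0, through_origin=True)
        slope = float(np.sum(x * y)) / sxx
        resid = y - slope * x
        dof = len(x) - 1
        stderr = math.sqrt(float(np.sum(resid**2)) / dof / sxx) if dof > 0 else math.nan
        return LinearRateFit(k_cat=slope, stderr=stderr, intercept=0.0, through_origin=True)
    fit = stats.linregress(x, y)
    return LinearRateFit(k_cat=float(fit.slope), stderr=float(fit.stderr),
                         intercept=float(fit.intercept), through_origin=False)
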