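"""Cell-level quantification: concentrations, ParB partitioning, shape.

Covers the arithmetic that turns molecule counts into intracellular
concentrations, the chromosome mass into a DNA concentration, per-cell
segment fluorescence profiles into the fraction of ParB residing in the
partition complex, a cell-population fluorescence histogram into its
autofluorescence/expressing split, and fluorescent-object point sets into
aspect-ratio (compaction) scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .constants import AVOGADRO

__all__ = [
    "AbundanceRecord",
    "PartitionFraction",
    "BimodalFit",
    "ARRecord",
    "molecules_to_concentration",
    "dna_concentration",
    "partition_fraction",
    "fit_bimodal_gaussian",
    "aspect_ratio",
    "bin_decompaction_by_position",
]


@dataclass
class AbundanceRecord:
    molecules: float | None
    moles: float
    volume_fl: float
    concentration_uM: float


@dataclass
class PartitionFraction:
    fraction: float            # fraction of signal in the partition complex
    diffuse_fraction: float
    ok: bool = True


@dataclass
class BimodalFit:
    means: tuple[float, float]     # ascending
    sds: tuple[float, float]
    weights: tuple[float, float]
    af_mean: float                 # lower-mean component = autofluorescence
    collapsed: bool
    converged: bool


@dataclass
class ARRecord:
    aspect_ratio: float
    major_length: float
    minor_length: float
    decompacted: bool
    ok: bool = True
    relative_position: float | None = None
    cutoff: float = 1.5


# ---------------------------------------------------------------------------


def molecules_to_concentration(
    molecules: float | None = None,
    volume_fl: float = 0.25,
    moles: float | None = None,
) -> AbundanceRecord:
    """Concentration (uM) of N molecules (or given moles) in a volume (fL).

    concentration = moles / volume; 1 fL = 1e-15 L, so
    uM = moles / (V_fl * 1e-15) * 1e6.
    """
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    if moles is None:
        if molecules is None or molecules < 0:
            raise ValueError("provide molecules >= 0 or moles")
        moles = molecules / AVOGADRO
    conc_uM = moles / (volume_fl * 1e-15) * 1e6
    return AbundanceRecord(molecules=molecules, moles=moles,
                           volume_fl=volume_fl, concentration_uM=conc_uM)


def dna_concentration(
    bp: float = 4e6,
    mass_per_bp_da: float = 650.0,
    volume_ml: float = 2.5e-13,
) -> float:
    """Intracellular DNA concentration in mg/ml.

    mass = bp * (Da per bp) / Avogadro grams; concentration = mass / volume.
    Defaults are one 4-Mbp chromosome at 650 Da/bp in a 0.25 fL cell.
    """
    if bp < 0 or mass_per_bp_da <= 0 or volume_ml <= 0:
        raise ValueError("invalid inputs")
    mass_g = bp * mass_per_bp_da / AVOGADRO
    return mass_g / volume_ml * 1000.0


def partition_fraction(fluorescence, area) -> PartitionFraction:
    """Fraction of a cell's fluorescent signal residing in the focus.

    Segments are ranked by fluorescence density (signal/area); the mean
    density of the lowest decile (ceil(0.1 n) segments, density ties broken
    by segment index) estimates the freely-diffusing concentration, which
    scaled by the total cell area gives the diffuse signal.  The partition
    fraction is 1 - diffuse/total.  Invariant to overall intensity scaling.
    """
    f = np.asarray(fluorescence, dtype=float)
    a = np.asarray(area, dtype=float)
    if len(f) != len(a):
        raise ValueError("fluorescence and area must have equal length")
    if len(f) < 10:
        raise ValueError("need at least 10 segments")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    total = float(f.sum())
    if total <= 0:
        return PartitionFraction(fraction=math.nan, diffuse_fraction=math.nan, ok=False)
    density = f / a
    order = np.lexsort((np.arange(len(f)), density))  # stable in segment index
    k = math.ceil(0.1 * len(f))
    diffuse_density = float(density[order[:k]].mean())
    diffuse = diffuse_density * float(a.sum())
    frac = 1.0 - diffuse / total
    return PartitionFraction(fraction=frac, diffuse_fraction=diffuse / total)


def fit_bimodal_gaussian(values, min_n: int = 100, random_state: int = 0) -> BimodalFit:
    """Two-component Gaussian mixture by maximum likelihood (EM).

    Components are ordered by ascending mean; the lower one is interpreted
    as the autofluorescence population.  Components whose means are closer
    than the smaller component SD are reported as collapsed (the input is
    effectively unimodal).
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(v) < min_n:
        raise ValueError(f"need at least {min_n} values")
    gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state)
    try:
        gm.fit(v)
        converged = bool(gm.converged_)
    except ValueError:
        return BimodalFit(means=(math.nan,) * 2, sds=(math.nan,) * 2,
                          weights=(math.nan,) * 2, af_mean=math.nan,
                          collapsed=True, converged=False)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    # two equal-SD Gaussians are unimodal when their means are closer than
    # ~2 SD; treat such fits (and vanishing components) as collapsed
    collapsed = (means[1] - means[0]) < (sds[0] + sds[1]) or min(weights) < 0.01
    return BimodalFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        af_mean=float(means[0]),
        collapsed=bool(collapsed),
        converged=converged,
    )


def aspect_ratio(
    points,
    weights=None,
    cutoff: float = 1.5,
    relative_position: float | None = None,
) -> ARRecord:
    """Aspect ratio of a fluorescent object from its (weighted) point set.

    Axis lengths come from the ellipse with matching second central
    moments: 4*sqrt(eigenvalue) per axis, so AR = sqrt(lambda_max /
    lambda_min) -- invariant to rotation, translation and uniform scaling
    of intensities.  AR > ``cutoff`` (default 1.5) flags a decompacted
    (stretched) object.  Degenerate (collinear or tiny) point sets return
    ``ok=False``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        return ARRecord(aspect_ratio=math.nan, major_length=math.nan,
                        minor_length=math.nan, decompacted=False, ok=False,
                        relative_position=relative_position, cutoff=cutoff)
    w = None if weights is None else np.asarray(weights, dtype=float)
    cov = np.cov(pts.T, aweights=w)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0 or not np.all(np.isfinite(evals)):
        return ARRecord(aspect_ratio=math.nan, major_length=math.nan,
                        minor_length=math.nan, decompacted=False, ok=False,
                        relative_position=relative_position, cutoff=cutoff)
    minor = 4.0 * math.sqrt(evals[0])
    major = 4.0 * math.sqrt(evals[1])
    ar = major / minor
    return ARRecord(aspect_ratio=ar, major_length=major, minor_length=minor,
                    decompacted=ar > cutoff, ok=True,
                    relative_position=relative_position, cutoff=cutoff)


def bin_decompaction_by_position(records, n_bins: int = 10):
    """Fraction of decompacted objects per relative-cell-position bin.

    ``records`` are :class:`ARRecord` with ``relative_position`` in [0, 1]
    (old pole = 0).  Returns (bin_centers, fraction, counts).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    frac = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    usable = [r for r in records if r.ok and r.relative_position is not None]
    for b in range(n_bins):
        in_bin = [r for r in usable
                  if edges[b] <= r.relative_position < edges[b + 1]
                  or (b == n_bins - 1 and r.relative_position == 1.0)]
        counts[b] = len(in_bin)
        if in_bin:
            frac[b] = np.mean([r.decompacted for r in in_bin])
    return centers, frac, counts
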