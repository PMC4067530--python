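"""Spot-table linking, phase detection and diffusion estimation.

Input is a table of detected fluorescent-spot positions (<= 2 partition
complexes per cell per frame, cell coordinates, old pole at x = 0).  The
module links spots into two trajectories, finds the directed "fast" phase of
segregation, extracts the three slow-phase segments used for diffusion
estimation, and estimates diffusion coefficients from displacement Gaussians
or MSD fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinkedTracks",
    "FastPhase",
    "PhaseAnnotation",
    "Segments",
    "DiffusionEstimate",
    "link_two_spots",
    "detect_fast_phase",
    "run_metrics",
    "extract_segments",
    "estimate_D_gaussian",
    "estimate_D_msd",
]


class MalformedInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


@dataclass
class LinkedTracks:
    """Two ordered trajectories for one cell; NaN marks a gap frame."""

    frames: np.ndarray          # frame indices, strictly increasing
    t_s: np.ndarray
    positions: np.ndarray       # shape (n_frames, 2 tracks, 2 coords), NaN gaps

    def track(self, k: int) -> np.ndarray:
        return self.positions[:, k, :]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def link_two_spots(spots: pd.DataFrame) -> LinkedTracks:
    """Link <=2 spots per frame into two trajectories for one cell.

    Per frame, the assignment minimising the summed displacement relative to
    the last known position of each track is chosen; single-spot frames
    inherit the nearer previous label; gap frames keep NaN.  Spots within a
    frame are pre-sorted by (x, y), which makes the result invariant to
    their input order, and exact cost ties keep the sorted (no-swap)
    labelling.
    """
    required = {"frame", "t_s", "x_um", "y_um"}
    missing = required - set(spots.columns)
    if missing:
        raise MalformedInputError(f"spot table lacks columns {sorted(missing)}")

    frames = np.sort(spots["frame"].unique())
    t_by_frame = spots.groupby("frame")["t_s"].first()
    positions = np.full((len(frames), 2, 2), np.nan)
    last_known: list[np.ndarray | None] = [None, None]

    for fi, f in enumerate(frames):
        rows = spots.loc[spots["frame"] == f, ["x_um", "y_um"]].to_numpy()
        if len(rows) > 2:
            raise MalformedInputError(f"frame {f}: {len(rows)} spots (max 2)")
        rows = rows[np.lexsort((rows[:, 1], rows[:, 0]))]

        def cost(spot, track):
            if last_known[track] is None:
                return 0.0
            return float(np.hypot(*(spot - last_known[track])))

        if len(rows) == 2:
            straight = cost(rows[0], 0) + cost(rows[1], 1)
            swapped = cost(rows[0], 1) + cost(rows[1], 0)
            pairing = ((0, 0), (1, 1)) if straight <= swapped else ((0, 1), (1, 0))
            for si, tk in pairing:
                positions[fi, tk] = rows[si]
                last_known[tk] = rows[si]
        elif len(rows) == 1:
            tk = 0 if cost(rows[0], 0) <= cost(rows[0], 1) else 1
            positions[fi, tk] = rows[0]
            last_known[tk] = rows[0]

    return LinkedTracks(
        frames=frames,
        t_s=t_by_frame.loc[frames].to_numpy(dtype=float),
        positions=positions,
    )


# ---------------------------------------------------------------------------
# fast-phase detection
# ---------------------------------------------------------------------------


@dataclass
class FastPhase:
    detected: bool
    run_start_idx: int | None = None
    run_end_idx: int | None = None
    smoothed: np.ndarray | None = None
    curvature: np.ndarray | None = None


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="valid")
    return out[: len(x)] if len(out) > len(x) else out


def detect_fast_phase(
    t: np.ndarray,
    x: np.ndarray,
    window: int = 5,
    curvature_threshold_sd: float = 4.0,
    min_run_length: float = 0.25,
) -> FastPhase:
    """Locate the directed run within a long-axis trajectory.

    The trace is linearly interpolated onto its uniform frame grid, smoothed
    by a ``window``-frame moving average, and its curvature evaluated with
    the wide-stencil second difference ``x[i+w] - 2 x[i] + x[i-w]`` (a
    smoothed second derivative whose extrema fall exactly on the change
    points of an ideal ramp).  The inflection pair bracketing the run is the
    (curvature peak, curvature trough) pair, each exceeding
    ``curvature_threshold_sd`` robust SDs, that covers the longest distance
    travelled; pairs covering less than ``min_run_length`` (um) are
    rejected, and ties prefer the shorter interval.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n != len(t):
        raise MalformedInputError("t and x must have equal length")
    w = max(1, int(window))
    if n < 2 * w + 3:
        return FastPhase(detected=False)

    # fill gaps on the uniform grid
    idx = np.arange(n, dtype=float)
    good = np.isfinite(x)
    if good.sum() < 2 * w + 3:
        return FastPhase(detected=False)
    xf = np.interp(idx, idx[good], x[good])
    xs = _moving_average(xf, w)

    curv = np.full(n, np.nan)
    curv[w:-w] = xs[2 * w:] - 2.0 * xs[w:-w] + xs[: -2 * w]
    # Localization-noise scale from the raw lag-1 second difference: linear
    # (and flat) stretches contribute nothing, so its robust SD is
    # sqrt(6) * sigma_noise regardless of how much of the trace is ramp.
    d2raw = xf[2:] - 2.0 * xf[1:-1] + xf[:-2]
    mad = np.median(np.abs(d2raw - np.median(d2raw)))
    sigma_noise = 1.4826 * mad / math.sqrt(6.0)
    # wide-stencil curvature of the w-averaged trace has noise SD ~ sqrt(6/w)
    thr = curvature_threshold_sd * math.sqrt(6.0 / w) * sigma_noise

    cand = np.arange(w, n - w)
    peaks = [i for i in cand if curv[i] > thr]
    troughs = [i for i in cand if curv[i] < -thr]
    # collapse consecutive candidates to local extrema
    peaks = _local_extrema(curv, peaks, sign=+1)
    troughs = _local_extrema(curv, troughs, sign=-1)

    best = None
    for p in peaks:
        for q in troughs:
            if q <= p:
                continue
            dist = xs[q] - xs[p]
            if dist < min_run_length:
                continue
            key = (dist, -(q - p))
            if best is None or key > best[0]:
                best = (key, p, q)
    if best is None:
        return FastPhase(detected=False, smoothed=xs, curvature=curv)
    _, p, q = best
    return FastPhase(detected=True, run_start_idx=int(p), run_end_idx=int(q),
                     smoothed=xs, curvature=curv)


def _local_extrema(curv, indices, sign):
    """Reduce runs of adjacent threshold-crossing indices to their extremum."""
    out = []
    group: list[int] = []
    for i in indices:
        if group and i != group[-1] + 1:
            out.append(max(group, key=lambda j: sign * curv[j]))
            group = []
        group.append(i)
    if group:
        out.append(max(group, key=lambda j: sign * curv[j]))
    return out


# ---------------------------------------------------------------------------
# run metrics
# ---------------------------------------------------------------------------


@dataclass
class PhaseAnnotation:
    """Derived metrics of one detected run (the fast phase)."""

    run_start_idx: int
    run_end_idx: int
    x_start: float
    x_finish: float
    run_length: float          # um, |x(end) - x(start)| along the long axis
    run_period: float          # s
    speed: float               # um/s
    x0_appearance: float | None = None
    short_axis_by_phase: dict = field(default_factory=dict)


def run_metrics(
    t: np.ndarray,
    x: np.ndarray,
    phase: FastPhase,
    y: np.ndarray | None = None,
    x0_appearance: float | None = None,
) -> PhaseAnnotation:
    """Complete a :class:`PhaseAnnotation` from a detected fast phase."""
    if not phase.detected:
        raise ValueError("no run detected; cannot compute run metrics")
    i, j = phase.run_start_idx, phase.run_end_idx
    if not i < j:
        raise ValueError("run_start_idx must precede run_end_idx")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    run_length = float(abs(x[j] - x[i]))
    run_period = float(t[j] - t[i])
    if run_period <= 0:
        raise ValueError("zero-duration run")
    short = {}
    if y is not None:
        y = np.asarray(y, dtype=float)
        short = {
            "slow": np.diff(y[: i + 1]),
            "fast": np.diff(y[i : j + 1]),
            "anchored": np.diff(y[j:]),
        }
    return PhaseAnnotation(
        run_start_idx=i,
        run_end_idx=j,
        x_start=float(x[i]),
        x_finish=float(x[j]),
        run_length=run_length,
        run_period=run_period,
        speed=run_length / run_period,
        x0_appearance=x0_appearance,
        short_axis_by_phase=short,
    )


# ---------------------------------------------------------------------------
# slow-phase segments
# ---------------------------------------------------------------------------


@dataclass
class Segments:
    """Frame-index arrays of the three slow-phase segments.

    segment1: single complex, detached from the old pole (x >= pole margin);
    segment2: pole-proximal complex, from ``delay_s`` after visible
    separation until it returns within the pole margin;
    segment3: pole-distal complex, longest stretch confined within a
    ``box_width`` window along the long axis (no net directed motion).
    """

    segment1: np.ndarray
    segment2: np.ndarray
    segment3: np.ndarray
    separation_frame_idx: int | None


def extract_segments(
    linked: LinkedTracks,
    frame_interval: float,
    pole_margin: float = 0.32,
    delay_s: float = 60.0,
    box_width: float = 0.5,
    separation_threshold: float = 0.25,
) -> Segments:
    """Apply the three slow-phase segment rules to a linked two-spot record.

    "Visibly separated" is the first frame where both spots are present and
    at least ``separation_threshold`` um apart (about twice the localization
    SD).  All thresholds are in um and configurable.
    """
    pos = linked.positions
    x = pos[:, :, 0]
    present = np.isfinite(x)
    both = present.all(axis=1)
    n = linked.n_frames

    sep_idx = None
    dist = np.hypot(pos[:, 0, 0] - pos[:, 1, 0], pos[:, 0, 1] - pos[:, 1, 1])
    for i in range(n):
        if both[i] and dist[i] >= separation_threshold:
            sep_idx = i
            break

    first_two = int(np.argmax(both)) if both.any() else n

    # segment 1: single-spot frames before duplication, away from the pole
    one_spot = present.sum(axis=1) == 1
    seg1 = []
    for i in range(first_two):
        if one_spot[i]:
            xi = x[i, present[i]][0]
            if xi >= pole_margin:
                seg1.append(i)
    seg1 = np.asarray(seg1, dtype=int)

    seg2 = np.asarray([], dtype=int)
    seg3 = np.asarray([], dtype=int)
    if sep_idx is not None:
        delay_frames = math.ceil(delay_s / frame_interval)
        start = sep_idx + delay_frames
        if start < n:
            # track means over frames where both are present
            mean_x = np.nanmean(np.where(both[:, None], x, np.nan), axis=0)
            proximal = int(np.argmin(mean_x))
            distal = 1 - proximal

            idxs = []
            for i in range(start, n):
                if not present[i, proximal]:
                    continue
                if x[i, proximal] < pole_margin:
                    break
                idxs.append(i)
            seg2 = np.asarray(idxs, dtype=int)

            dist_frames = [i for i in range(start, n) if present[i, distal]]
            seg3 = _longest_confined(x[:, distal], dist_frames, box_width)

    return Segments(segment1=seg1, segment2=seg2, segment3=seg3,
                    separation_frame_idx=sep_idx)


def _longest_confined(x, frames, box_width):
    """Longest contiguous run of ``frames`` with range(x) <= box_width."""
    best: tuple[int, int] | None = None
    m = len(frames)
    for a in range(m):
        lo = hi = x[frames[a]]
        for b in range(a, m):
            if frames[b] != frames[a] + (b - a):
                break  # contiguity broken by a gap
            lo = min(lo, x[frames[b]])
            hi = max(hi, x[frames[b]])
            if hi - lo > box_width:
                break
            if best is None or (b - a) > (best[1] - best[0]):
                best = (a, b)
    if best is None:
        return np.asarray([], dtype=int)
    return np.asarray(frames[best[0] : best[1] + 1], dtype=int)


# ---------------------------------------------------------------------------
# diffusion estimation
# ---------------------------------------------------------------------------


@dataclass
class DiffusionEstimate:
    D: float                   # um^2/s
    stderr: float
    method: str                # gaussian_displacement | msd_linear
    ok: bool = True
    segment: int | None = None
    intercept: float | None = None


def estimate_D_gaussian(
    displacements: np.ndarray,
    dt: float,
    min_n: int = 50,
    segment: int | None = None,
) -> DiffusionEstimate:
    """Fit a zero-mean Gaussian to 1-D displacements at lag ``dt``.

    The maximum-likelihood variance of a zero-mean Gaussian is the mean
    square displacement, and D = Var / (2 dt) for 1-D normal diffusion.
    """
    d = np.asarray(displacements, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < min_n:
        raise ValueError(f"need at least {min_n} displacements, got {len(d)}")
    var = float(np.mean(d**2))
    if var == 0.0:
        return DiffusionEstimate(D=0.0, stderr=np.nan, ok=False,
                                 method="gaussian_displacement", segment=segment)
    var_err = var * math.sqrt(2.0 / len(d))
    return DiffusionEstimate(
        D=var / (2.0 * dt),
        stderr=var_err / (2.0 * dt),
        method="gaussian_displacement",
        segment=segment,
    )


def msd(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged 1-D MSD for lags 1..max_lag (overlapping pairs)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = x[k:] - x[:-k]
        d = d[np.isfinite(d)]
        if len(d) == 0:
            out[k - 1] = np.nan
        else:
            out[k - 1] = np.mean(d**2)
    return out


def estimate_D_msd(
    x: np.ndarray,
    dt: float,
    n_points: int = 4,
    convention: str = "standard",
    segment: int | None = None,
) -> DiffusionEstimate:
    """OLS line through the first ``n_points`` MSD lags, free offset.

    ``convention='standard'`` reads the slope as 2D (1-D diffusion);
    ``convention='slope'`` reports D = slope directly (the alternative
    convention sometimes used with MSD = D t + C).  The free offset absorbs
    the localization-noise floor.
    """
    x = np.asarray(x, dtype=float)
    if np.isfinite(x).sum() < n_points + 1:
        raise ValueError("insufficient data for the requested number of lags")
    m = msd(x, n_points)
    if np.isnan(m).any():
        raise ValueError("could not compute all requested MSD lags")
    lags = dt * np.arange(1, n_points + 1)
    fit = stats.linregress(lags, m)
    factor = 2.0 if convention == "standard" else 1.0
    if convention not in ("standard", "slope"):
        raise ValueError("convention must be 'standard' or 'slope'")
    return DiffusionEstimate(
        D=fit.slope / factor,
        stderr=(fit.stderr if fit.stderr is not None else np.nan) / factor,
        method="msd_linear",
        intercept=float(fit.intercept),
        segment=segment,
    )
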