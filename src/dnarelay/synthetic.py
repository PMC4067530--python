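"""Seeded generators for every input class the analysis pipeline consumes.

Each generator returns ``(data, truth)`` where ``truth`` is the sidecar
ground-truth dictionary that downstream recovery tests compare against
(never hard-coded numbers).  The same seed always reproduces the same
output.  Defaults mirror the study conditions: 2-s/180-s locus-fluctuation
movies, 20-s two-spot segregation movies with a ~1 um run at ~220 nm/min,
plate-reader Michaelis-Menten designs, and 20-nm localization noise where
spot positions are emulated.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .bd import bd_step, spring_force
from .kinetics import michaelis_menten

__all__ = [
    "gen_locus_fluctuation",
    "gen_free_diffusion",
    "gen_multiphasic_two_spot",
    "gen_mm_kinetics",
    "gen_nadh_timecourse",
    "gen_segment_profile",
    "gen_elliptical_region",
    "GENERATORS",
]


def gen_locus_fluctuation(
    n_cells: int = 641,
    n_frames: int = 90,
    frame_interval: float = 2.0,
    sigma_long: float = 0.064,
    sigma_short: float = 0.038,
    D_A: float = 0.01,
    l0: float = 2.6,
    w0: float = 0.4,
    dt: float = 0.01,
    seed: int = 0,
):
    """Chromosomal-locus trajectories fluctuating in anisotropic harmonic wells.

    One locus per cell, integrated with the package's second-order scheme at
    step ``dt`` and subsampled at ``frame_interval`` (the imaging cadence);
    per-cell equilibrium points are randomized inside the cell.  ``sigma``
    is the observed fluctuation SD (localization error is considered part
    of it, as in the fitted experimental values), so no extra position
    noise is added.
    """
    rng = np.random.default_rng(seed)
    mx = min(4.0 * sigma_long, 0.45 * l0)
    my = min(4.0 * sigma_short, 0.45 * w0)
    eq = np.column_stack(
        [
            rng.uniform(mx, l0 - mx, n_cells),
            rng.uniform(-w0 / 2 + my, w0 / 2 - my, n_cells),
        ]
    )
    k_over_kT = np.array([1.0 / sigma_long**2, 1.0 / sigma_short**2])
    # start from the stationary (Boltzmann) distribution
    pos = eq + rng.normal(size=(n_cells, 2)) * np.array([sigma_long, sigma_short])
    sub = int(round(frame_interval / dt))

    records = np.empty((n_frames, n_cells, 2))
    records[0] = pos
    for f in range(1, n_frames):
        for _ in range(sub):
            force, deriv = spring_force(pos, eq, k_over_kT)
            pos = bd_step(pos, force, deriv, D_A, dt, rng)
        records[f] = pos

    frames = np.arange(n_frames)
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_cells), n_frames),
            "frame": np.tile(frames, n_cells),
            "t_s": np.tile(frames * frame_interval, n_cells),
            "x_um": records[:, :, 0].T.ravel(),
            "y_um": records[:, :, 1].T.ravel(),
        }
    )
    truth = {
        "sigma_long": sigma_long,
        "sigma_short": sigma_short,
        "D_A": D_A,
        "frame_interval": frame_interval,
        "n_cells": n_cells,
        "n_frames": n_frames,
    }
    return df, truth


def gen_free_diffusion(
    D: float = 1e-4,
    frame_interval: float = 20.0,
    n_frames: int = 101,
    n_tracks: int = 20,
    x0: float = 0.0,
    loc_noise: float = 0.0,
    seed: int = 0,
):
    """Pure 1-D Brownian tracks at diffusivity ``D`` (um^2/s)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * frame_interval), (n_tracks, n_frames - 1))
    x = np.concatenate([np.full((n_tracks, 1), x0), x0 + np.cumsum(steps, axis=1)], axis=1)
    if loc_noise > 0:
        x = x + rng.normal(0.0, loc_noise, x.shape)
    frames = np.arange(n_frames)
    df = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_tracks), n_frames),
            "frame": np.tile(frames, n_tracks),
            "t_s": np.tile(frames * frame_interval, n_tracks),
            "x_um": x.ravel(),
        }
    )
    truth = {"D": D, "frame_interval": frame_interval, "loc_noise": loc_noise}
    return df, truth


def gen_multiphasic_two_spot(
    n_cells: int = 1,
    frame_interval: float = 20.0,
    x0: float = 0.8,
    proximal_x: float = 0.3,
    slow_duration: float = 300.0,
    run_length: float = 1.0,
    speed_nm_min: float = 220.0,
    anchored_duration: float = 200.0,
    D_slow: float = 0.0,
    anchor_sd: float = 0.02,
    loc_noise: float = 0.02,
    l0: float = 2.6,
    w0: float = 0.4,
    seed: int = 0,
):
    """Two-spot segregation movies with slow / fast (directed) / anchored phases.

    The distal complex idles near ``x0`` (optionally diffusing at
    ``D_slow``), runs toward the new pole at ``speed_nm_min`` covering
    ``run_length``, then stays confined (SD ``anchor_sd``); the proximal
    complex remains near the old pole.  All positions carry Gaussian
    localization noise ``loc_noise`` (um).  The sidecar truth records the
    continuous change-point times and their nearest frame indices.
    """
    rng = np.random.default_rng(seed)
    speed = speed_nm_min / 1000.0 / 60.0  # um/s
    run_duration = run_length / speed
    t1, t2 = slow_duration, slow_duration + run_duration
    total = t2 + anchored_duration
    n_frames = int(np.floor(total / frame_interval)) + 1
    t = np.arange(n_frames) * frame_interval

    rows = []
    for cell in range(n_cells):
        # distal complex: piecewise mean path
        mean_x = np.where(t < t1, x0, np.where(t < t2, x0 + speed * (t - t1), x0 + run_length))
        wobble = np.zeros(n_frames)
        if D_slow > 0:
            steps = rng.normal(0.0, np.sqrt(2.0 * D_slow * frame_interval), n_frames - 1)
            wobble[1:] = np.cumsum(steps)
        anchored = t >= t2
        x_dist = mean_x + wobble + np.where(anchored, rng.normal(0.0, anchor_sd, n_frames), 0.0)
        x_dist = x_dist + rng.normal(0.0, loc_noise, n_frames)
        y_dist = rng.normal(0.0, loc_noise, n_frames)
        x_prox = proximal_x + rng.normal(0.0, loc_noise, n_frames)
        y_prox = rng.normal(0.0, loc_noise, n_frames)
        for f in range(n_frames):
            rows.append((cell, f, t[f], np.clip(x_prox[f], 0, l0), y_prox[f], 0))
            rows.append((cell, f, t[f], np.clip(x_dist[f], 0, l0), y_dist[f], 1))

    df = pd.DataFrame(rows, columns=["cell_id", "frame", "t_s", "x_um", "y_um", "spot_id"])
    truth = {
        "run_start_time": t1,
        "run_end_time": t2,
        "run_start_frame": int(round(t1 / frame_interval)),
        "run_end_frame": int(round(t2 / frame_interval)),
        "run_length": run_length,
        "run_period": run_duration,
        "speed_um_s": speed,
        "speed_nm_min": speed_nm_min,
        "frame_interval": frame_interval,
        "loc_noise": loc_noise,
        "x0": x0,
        "l0": l0,
        "w0": w0,
    }
    return df, truth


def gen_mm_kinetics(
    vmax: float = 120.0,
    K: float = 80.0,
    S_grid=(10.0, 20.0, 40.0, 80.0, 160.0, 320.0),
    noise_frac: float = 0.05,
    n_reps: int = 1,
    seed: int = 0,
):
    """Substrate-dependence tables v = Vmax S/(K+S) with multiplicative noise."""
    rng = np.random.default_rng(seed)
    S = np.asarray(S_grid, dtype=float)
    rows = []
    for rep in range(n_reps):
        v = michaelis_menten(S, vmax, K)
        if noise_frac > 0:
            v = v * (1.0 + noise_frac * rng.standard_normal(len(S)))
        v = np.clip(v, 0.0, None)
        for s, vi in zip(S, v):
            rows.append((rep, s, vi))
    df = pd.DataFrame(rows, columns=["rep", "S", "v"])
    truth = {"vmax": vmax, "K": K, "noise_frac": noise_frac, "n_reps": n_reps}
    return df, truth


def gen_nadh_timecourse(
    rate_uM_per_hr: float = 60.0,
    nadh_standard_uM_per_abs: float = 160.0,
    duration_min: float = 30.0,
    a0: float = 1.0,
    noise_sd: float = 1e-4,
    control_rate_uM_per_hr: float = 0.0,
    seed: int = 0,
):
    """NADH-coupled absorbance time courses (A340 declines as ATP turns over).

    The sample slope is -(rate + control)/standard per hour; the matched
    control well carries only the spontaneous component.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 0.5, 1.0)
    slope = -(rate_uM_per_hr + control_rate_uM_per_hr) / nadh_standard_uM_per_abs / 60.0
    control_slope = -control_rate_uM_per_hr / nadh_standard_uM_per_abs / 60.0
    a = a0 + slope * t + rng.normal(0.0, noise_sd, len(t))
    ctrl = a0 + control_slope * t + rng.normal(0.0, noise_sd, len(t))
    df = pd.DataFrame({"t_min": t, "A340": a, "A340_control": ctrl})
    truth = {
        "rate_uM_per_hr": rate_uM_per_hr,
        "slope_abs_per_min": slope,
        "control_slope_abs_per_min": control_slope,
        "nadh_standard_uM_per_abs": nadh_standard_uM_per_abs,
    }
    return df, truth


def gen_segment_profile(
    n_segments: int = 20,
    focus_fraction: float = 0.8,
    total_fluorescence: float = 1000.0,
    focus_segment: int | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
):
    """Per-cell segment fluorescence: one bright focus over diffuse background.

    The diffuse component spreads ``1 - focus_fraction`` of the signal
    uniformly per unit area; the focus adds the rest to one segment.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 <= focus_fraction <= 1.0:
        raise ValueError("focus_fraction must lie in [0, 1]")
    area = np.ones(n_segments)
    diffuse = (1.0 - focus_fraction) * total_fluorescence * area / area.sum()
    fluor = diffuse.copy()
    if focus_segment is None:
        focus_segment = n_segments // 2
    fluor[focus_segment] += focus_fraction * total_fluorescence
    if noise_frac > 0:
        fluor = fluor * (1.0 + noise_frac * rng.standard_normal(n_segments))
        fluor = np.clip(fluor, 0.0, None)
    truth = {"focus_fraction": focus_fraction, "focus_segment": focus_segment}
    return (fluor, area), truth


def gen_elliptical_region(
    n_points: int = 400,
    sd_major: float = 0.09,
    sd_minor: float = 0.03,
    angle_deg: float = 0.0,
    center=(0.0, 0.0),
    seed: int = 0,
):
    """Elliptical Gaussian point cloud standing in for a fluorescent object."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 2)) * np.array([sd_major, sd_minor])
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pts = pts @ rot.T + np.asarray(center, dtype=float)
    truth = {"aspect_ratio": sd_major / sd_minor, "sd_major": sd_major,
             "sd_minor": sd_minor, "angle_deg": angle_deg}
    return pts, truth


#: CLI dispatch table: kind -> generator.
GENERATORS: dict[str, Callable] = {
    "locus_fluctuation": gen_locus_fluctuation,
    "free_diffusion": gen_free_diffusion,
    "multiphasic_two_spot": gen_multiphasic_two_spot,
    "mm_kinetics": gen_mm_kinetics,
    "nadh_timecourse": gen_nadh_timecourse,
    "segment_profile": gen_segment_profile,
    "elliptical_region": gen_elliptical_region,
}
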