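"""Tests of spot linking, phase detection, segments and D estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dnarelay import synthetic, trajectory
from dnarelay.trajectory import (
    LinkedTracks,
    MalformedInputError,
    detect_fast_phase,
    estimate_D_gaussian,
    estimate_D_msd,
    extract_segments,
    link_two_spots,
    msd,
    run_metrics,
)


def _spot_frame(rows):
    return pd.DataFrame(rows, columns=["frame", "t_s", "x_um", "y_um"])


class TestLinking:
    def test_parallel_tracks_keep_identity(self):
        rows = []
        for f in range(10):
            rows.append((f, 20.0 * f, 0.3 + 0.01 * f, 0.0))
            rows.append((f, 20.0 * f, 0.8 + 0.01 * f, 0.0))
        linked = link_two_spots(_spot_frame(rows))
        assert np.allclose(linked.track(0)[:, 0], 0.3 + 0.01 * np.arange(10))
        assert np.allclose(linked.track(1)[:, 0], 0.8 + 0.01 * np.arange(10))

    def test_assignment_minimises_total_displacement(self):
        """Crossing-like geometry where swapping doubles the cost: no swap."""
        rows = [(0, 0.0, 0.4, 0.0), (0, 0.0, 0.6, 0.0),
                (1, 20.0, 0.45, 0.0), (1, 20.0, 0.62, 0.0)]
        linked = link_two_spots(_spot_frame(rows))
        # brute force both assignments for frame 1
        prev = np.array([[0.4, 0.0], [0.6, 0.0]])
        cur = np.array([[0.45, 0.0], [0.62, 0.0]])
        costs = {}
        for perm in itertools.permutations([0, 1]):
            costs[perm] = sum(np.hypot(*(cur[i] - prev[t])) for i, t in zip([0, 1], perm))
        best = min(costs, key=costs.get)
        assert best == (0, 1)
        assert linked.track(0)[1, 0] == pytest.approx(0.45)
        assert linked.track(1)[1, 0] == pytest.approx(0.62)

    def test_single_spot_frame_inherits_nearer_label(self):
        rows = [(0, 0.0, 0.4, 0.0), (0, 0.0, 1.2, 0.0),
                (1, 20.0, 1.25, 0.0)]
        linked = link_two_spots(_spot_frame(rows))
        assert np.isnan(linked.track(0)[1, 0])
        assert linked.track(1)[1, 0] == pytest.approx(1.25)

    def test_permutation_invariance_within_frame(self):
        rows = [(0, 0.0, 0.4, 0.0), (0, 0.0, 1.2, 0.0),
                (1, 20.0, 0.42, 0.0), (1, 20.0, 1.18, 0.0)]
        a = link_two_spots(_spot_frame(rows))
        b = link_two_spots(_spot_frame([rows[1], rows[0], rows[3], rows[2]]))
        assert np.allclose(a.positions, b.positions, equal_nan=True)

    def test_three_spots_rejected(self):
        rows = [(0, 0.0, 0.4, 0.0), (0, 0.0, 0.8, 0.0), (0, 0.0, 1.2, 0.0)]
        with pytest.raises(MalformedInputError):
            link_two_spots(_spot_frame(rows))


class TestFastPhase:
    def test_ideal_ramp_detected_exactly(self):
        t = np.arange(0, 800, 20.0)
        x = np.where(t < 300, 0.8, np.where(t < 580, 0.8 + (t - 300) / 280, 1.8))
        phase = detect_fast_phase(t, x)
        assert phase.detected
        ann = run_metrics(t, x, phase)
        assert ann.run_length == pytest.approx(1.0)
        assert ann.run_period == pytest.approx(280.0)
        assert ann.speed * 6e4 == pytest.approx(214.3, abs=0.1)  # nm/min

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_changepoints_within_two_frames(self, seed):
        df, truth = synthetic.gen_multiphasic_two_spot(seed=seed)
        g = df[df["spot_id"] == 1]
        phase = detect_fast_phase(g["t_s"].to_numpy(), g["x_um"].to_numpy())
        assert phase.detected
        assert abs(phase.run_start_idx - truth["run_start_frame"]) <= 2
        assert abs(phase.run_end_idx - truth["run_end_frame"]) <= 2

    def test_pure_noise_yields_no_run(self):
        rng = np.random.default_rng(4)
        x = 0.8 + rng.normal(0, 0.02, 60)
        assert not detect_fast_phase(np.arange(60) * 20.0, x).detected

    def test_zero_speed_fast_phase_yields_no_run(self):
        df, _ = synthetic.gen_multiphasic_two_spot(speed_nm_min=1e-6, run_length=1e-9,
                                                   seed=0)
        g = df[df["spot_id"] == 1]
        phase = detect_fast_phase(g["t_s"].to_numpy(), g["x_um"].to_numpy())
        assert not phase.detected

    def test_indices_invariant_under_time_shift_and_y_reflection(self):
        df, _ = synthetic.gen_multiphasic_two_spot(seed=3)
        g = df[df["spot_id"] == 1]
        t, x = g["t_s"].to_numpy(), g["x_um"].to_numpy()
        a = detect_fast_phase(t, x)
        b = detect_fast_phase(t + 500.0, x)
        assert (a.run_start_idx, a.run_end_idx) == (b.run_start_idx, b.run_end_idx)


class TestRunMetrics:
    def test_speed_is_length_over_period(self):
        t = np.arange(0, 800, 20.0)
        x = np.where(t < 300, 0.8, np.where(t < 582, 0.8 + (t - 300) / 282, 1.8))
        phase = detect_fast_phase(t, x)
        ann = run_metrics(t, x, phase)
        assert ann.speed == pytest.approx(ann.run_length / ann.run_period)

    def test_short_axis_displacements_same_law_in_slow_and_fast_phase(self):
        """Isotropic noise: fast-phase dy distribution matches slow-phase (KS)."""
        from scipy import stats

        df, truth = synthetic.gen_multiphasic_two_spot(anchored_duration=600.0, seed=8)
        g = df[df["spot_id"] == 1]
        t, x, y = (g[c].to_numpy() for c in ("t_s", "x_um", "y_um"))
        phase = detect_fast_phase(t, x)
        ann = run_metrics(t, x, phase, y=y)
        ks = stats.ks_2samp(ann.short_axis_by_phase["slow"],
                            ann.short_axis_by_phase["fast"])
        assert ks.pvalue > 0.01


def _linked_from_tracks(x0, x1, frame_interval=20.0):
    n = len(x0)
    pos = np.full((n, 2, 2), np.nan)
    pos[:, 0, 0] = x0
    pos[:, 1, 0] = x1
    pos[:, :, 1] = 0.0
    pos[np.isnan(pos[:, :, 0]), 1] = np.nan
    return LinkedTracks(frames=np.arange(n), t_s=np.arange(n) * frame_interval,
                        positions=pos)


class TestSegments:
    def test_single_spot_near_pole_gives_empty_segment1(self):
        x0 = np.full(10, 0.25)  # single complex within 320 nm of the pole
        linked = _linked_from_tracks(x0, np.full(10, np.nan))
        segs = extract_segments(linked, frame_interval=20.0)
        assert len(segs.segment1) == 0

    def test_segment2_starts_one_minute_after_separation(self):
        n = 30
        prox = np.full(n, 0.5)
        dist = np.concatenate([np.full(10, np.nan), np.full(n - 10, 1.2)])
        linked = _linked_from_tracks(prox, dist)
        segs = extract_segments(linked, frame_interval=20.0)
        assert segs.separation_frame_idx == 10
        assert segs.segment2[0] == 13  # 60 s = 3 frames after separation

    def test_segment3_is_longest_confined_window(self):
        n = 60
        rng = np.random.default_rng(0)
        dist = np.empty(n)
        dist[:45] = 1.0 + rng.uniform(-0.15, 0.15, 45)  # confined in ~0.3 um
        dist[45:] = 1.0 + np.arange(15) * 0.1           # 1.5-um run
        prox = np.full(n, 0.5)
        linked = _linked_from_tracks(prox, dist)
        segs = extract_segments(linked, frame_interval=20.0, delay_s=60.0,
                                separation_threshold=0.25)
        start = segs.separation_frame_idx + 3
        assert segs.segment3[0] >= start
        assert segs.segment3[-1] <= 45 + 5  # ends when the run exceeds the box
        assert np.ptp(dist[segs.segment3]) <= 0.5

    def test_segment_rules_match_brute_force_on_random_inputs(self):
        """The confined-window scan equals an O(n^2) reference."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(10, 40)
            x = np.cumsum(rng.normal(0, 0.1, n)) + 1.0
            frames = list(range(n))
            got = trajectory._longest_confined(x, frames, 0.5)
            # brute force over all contiguous windows
            best = (0, -1)
            for a in range(n):
                for b in range(a, n):
                    if np.ptp(x[a:b + 1]) <= 0.5 and (b - a) > (best[1] - best[0]):
                        best = (a, b)
            expect = np.arange(best[0], best[1] + 1)
            assert np.array_equal(got, expect)


class TestDiffusionEstimates:
    def test_gaussian_estimator_exact_inversion(self):
        # variance exactly 2 D dt -> exact D
        D, dt = 1e-4, 20.0
        s = np.sqrt(2 * D * dt)
        d = np.array([s, -s] * 50)
        est = estimate_D_gaussian(d, dt)
        assert est.D == pytest.approx(D)

    def test_gaussian_estimator_recovers_generator_truth(self):
        df, truth = synthetic.gen_free_diffusion(D=1e-4, n_tracks=20, n_frames=101,
                                                 seed=2)
        disp = np.concatenate([np.diff(g["x_um"].to_numpy())
                               for _, g in df.groupby("track_id")])
        assert len(disp) == 2000
        est = estimate_D_gaussian(disp, truth["frame_interval"])
        assert est.D == pytest.approx(truth["D"], rel=0.10)

    def test_doubling_lag_doubles_fitted_variance(self, rng):
        d = rng.normal(0, 1.0, 5000)
        e1 = estimate_D_gaussian(d, 10.0)
        e2 = estimate_D_gaussian(d, 20.0)
        assert e1.D == pytest.approx(2 * e2.D)

    def test_degenerate_displacements_flagged(self):
        est = estimate_D_gaussian(np.zeros(100), 20.0)
        assert not est.ok and est.D == 0.0

    def test_msd_matches_brute_force_double_loop(self, rng):
        x = np.cumsum(rng.normal(0, 0.1, 50))
        got = msd(x, 6)
        for k in range(1, 7):
            ref = np.mean([(x[i + k] - x[i]) ** 2 for i in range(len(x) - k)])
            assert got[k - 1] == pytest.approx(ref)

    def test_msd_estimator_recovers_generator_truth(self):
        df, truth = synthetic.gen_free_diffusion(D=1e-4, n_tracks=1, n_frames=1001,
                                                 seed=3)
        est = estimate_D_msd(df["x_um"].to_numpy(), truth["frame_interval"])
        assert est.D == pytest.approx(truth["D"], rel=0.15)

    def test_msd_conventions_differ_by_factor_two(self):
        df, _ = synthetic.gen_free_diffusion(D=1e-4, n_tracks=1, n_frames=201, seed=4)
        x = df["x_um"].to_numpy()
        std = estimate_D_msd(x, 20.0, convention="standard")
        printed = estimate_D_msd(x, 20.0, convention="slope")
        assert printed.D == pytest.approx(2 * std.D)

    def test_static_trajectory_with_noise_gives_offset_not_slope(self, rng):
        x = 1.0 + rng.normal(0, 0.02, 500)  # localization noise only
        est = estimate_D_msd(x, 20.0)
        assert abs(est.D) < 1e-6
        assert est.intercept == pytest.approx(2 * 0.02**2, rel=0.3)

    def test_both_estimators_agree_on_long_pure_diffusion(self):
        df, truth = synthetic.gen_free_diffusion(D=1e-4, n_tracks=1, n_frames=2001,
                                                 seed=5)
        x = df["x_um"].to_numpy()
        g = estimate_D_gaussian(np.diff(x), truth["frame_interval"])
        m = estimate_D_msd(x, truth["frame_interval"])
        assert g.D == pytest.approx(m.D, rel=0.25)
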