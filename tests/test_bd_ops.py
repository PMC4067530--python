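"""Unit tests of the elementary Brownian-dynamics operations."""

import math

import numpy as np
import pytest

from dnarelay import (
    ParADimer,
    PartitionComplex,
    SimState,
    SimulationConfig,
    bd_step,
    reflect,
    sample_correlated_noise,
    sample_rebinding_x,
    spring_force,
    update_bindings,
)
from dnarelay.bd import InvalidStateError, InternalConsistencyError


class TestCorrelatedNoise:
    def test_moments_match_analytic_covariance(self, rng):
        """Monte-Carlo covariance of (R0, R1) vs the closed form, 4 SE."""
        D, dt, n = 0.01, 0.001, 100_000
        r0, r1 = sample_correlated_noise(D, dt, rng, size=n)
        var0, var1 = 2 * D * dt, (2 / 3) * D * dt**3
        cov01 = D * dt**2
        # standard errors of second moments of Gaussians
        se_var0 = var0 * math.sqrt(2 / n)
        se_var1 = var1 * math.sqrt(2 / n)
        se_cov = math.sqrt((var0 * var1 + cov01**2) / n)
        assert abs(r0.mean()) < 4 * math.sqrt(var0 / n)
        assert abs(r1.mean()) < 4 * math.sqrt(var1 / n)
        assert abs(r0.var() - var0) < 4 * se_var0
        assert abs(r1.var() - var1) < 4 * se_var1
        assert abs(np.mean(r0 * r1) - cov01) < 4 * se_cov

    def test_covariance_matrix_positive_definite(self):
        D, dt = 1e-4, 1e-3
        m = np.array([[2 * D * dt, D * dt**2], [D * dt**2, (2 / 3) * D * dt**3]])
        det = np.linalg.det(m)
        assert det == pytest.approx(D**2 * dt**4 / 3, rel=1e-9)
        assert det > 0

    @pytest.mark.parametrize("D,dt", [(0.0, 1e-3), (-1.0, 1e-3), (1e-4, 0.0)])
    def test_invalid_parameters_rejected(self, rng, D, dt):
        with pytest.raises(ValueError):
            sample_correlated_noise(D, dt, rng)


class TestSpringForce:
    def test_restoring_direction_and_magnitude(self):
        # displaced by +sigma_long along x: |F| = k_sp * sigma, pointing back
        k_over_kT = (1 / 0.06**2, 1 / 0.04**2)
        kT = 4.18e-3  # pN*um
        force, deriv = spring_force([0.86, 0.0], [0.8, 0.0], k_over_kT, kT=kT)
        k_long = kT / 0.06**2  # pN/um
        assert force[0] == pytest.approx(-k_long * 0.06)
        assert force[0] < 0  # restoring: opposes the +x displacement
        assert force[1] == 0.0
        assert deriv[0] == pytest.approx(-k_long)

    def test_zero_at_equilibrium_and_axis_anisotropy(self):
        force, _ = spring_force([0.8, 0.1], [0.8, 0.1], (278.0, 625.0))
        assert np.all(force == 0)
        # same displacement on each axis: force ratio = (sigma_long/sigma_short)^2
        f, _ = spring_force([0.01, 0.01], [0.0, 0.0], (1 / 0.06**2, 1 / 0.04**2))
        assert f[1] / f[0] == pytest.approx((0.06 / 0.04) ** 2)


class TestBdStep:
    def test_free_diffusion_msd(self, rng):
        """With F = 0 the update is pure diffusion: MSD slope 2D, 3 SE."""
        D, dt, n = 1e-4, 1e-3, 10_000
        zeros = np.zeros(n)
        x = bd_step(zeros, zeros, zeros, D, dt, rng)
        msd = np.mean(x**2)
        se = 2 * D * dt * math.sqrt(2 / n)
        assert abs(msd - 2 * D * dt) < 3 * se

    def test_constant_force_drift(self, rng):
        """E[dx] per step = (D/kT) F dt for a constant force."""
        D, dt, kT, F, n = 1e-4, 1e-3, 4.18e-3, 0.5, 200_000
        x = bd_step(np.zeros(n), np.full(n, F), np.zeros(n), D, dt, rng, kT=kT)
        drift = (D / kT) * F * dt
        se = math.sqrt(2 * D * dt / n)
        assert abs(x.mean() - drift) < 3 * se

    def test_harmonic_well_stationary_sd(self, rng):
        """Boltzmann limit: long-run positional SD equals the configured sigma."""
        sigma, D, dt = 0.06, 0.01, 0.002
        k_over_kT = np.array([1 / sigma**2])
        pos = np.zeros(1000)
        samples = []
        # burn-in then sample every ~5 relaxation times
        tau_steps = int(sigma**2 / D / dt)
        for step in range(60 * tau_steps):
            force, deriv = spring_force(pos, np.zeros_like(pos), k_over_kT[0])
            pos = bd_step(pos, force, deriv, D, dt, rng)
            if step > 10 * tau_steps and step % (5 * tau_steps) == 0:
                samples.append(pos.copy())
        s = np.concatenate(samples)
        assert np.std(s) == pytest.approx(sigma, rel=0.05)


class TestReflect:
    def test_mirror_and_identity(self):
        assert reflect([-0.01, 0.0], 2.5, 0.4)[0] == pytest.approx(0.01)
        assert np.allclose(reflect([1.3, -0.1], 2.5, 0.4), [1.3, -0.1])
        assert reflect([1.0, 0.203], 2.5, 0.4)[1] == pytest.approx(0.197)

    def test_large_overshoot_folds_repeatedly(self):
        out = reflect([2.5 + 5.3, 0.0], 2.5, 0.4)
        assert 0 <= out[0] <= 2.5
        # idempotent
        assert np.allclose(reflect(out, 2.5, 0.4), out)


class TestRebinding:
    def test_inverse_cdf_endpoints_and_quartile(self):
        class FixedRng:
            def __init__(self, u):
                self.u = u

            def random(self, size=None):
                return self.u

        assert sample_rebinding_x(0.8, 2.6, FixedRng(0.0)) == pytest.approx(0.8)
        assert sample_rebinding_x(0.8, 2.6, FixedRng(1.0)) == pytest.approx(2.6)
        assert sample_rebinding_x(0.8, 2.6, FixedRng(0.25)) == pytest.approx(1.7)

    def test_mean_of_linear_density(self, rng):
        x_pc, l, n = 0.8, 2.6, 100_000
        x = sample_rebinding_x(x_pc, l, rng, size=n)
        mean = x_pc + (2 / 3) * (l - x_pc)
        var = (l - x_pc) ** 2 / 18  # second moment of the triangular density
        assert abs(x.mean() - mean) < 3 * math.sqrt(var / n)
        assert x.min() >= x_pc and x.max() <= l

    def test_no_rebinding_region_is_an_error(self, rng):
        with pytest.raises(InvalidStateError):
            sample_rebinding_x(2.6, 2.6, rng)


def _make_state(dimers, model="dna_relay", **cfg_kwargs):
    cfg = SimulationConfig(model=model, n_ParA=len(dimers), **cfg_kwargs)
    return SimState(config=cfg, complex=PartitionComplex(position=[0.8, 0.0]),
                    dimers=dimers)


class TestUpdateBindings:
    def test_capture_on_overlap_boundary_inclusive(self, rng):
        # center distance 0.051 with R_PC + R_ParA = 0.052: capture
        near = ParADimer(position=[0.851, 0.0], eq_point=[0.851, 0.0], state="dna_bound")
        far = ParADimer(position=[0.853, 0.0], eq_point=[0.853, 0.0], state="dna_bound")
        st = _make_state([near, far])
        update_bindings(st, st.config.dt, rng)
        assert near.state == "pc_bound" and far.state == "dna_bound"
        assert st.complex.bound_ids == {0}

    def test_zero_hydrolysis_rate_never_releases(self, rng):
        dim = ParADimer(position=[0.82, 0.0], eq_point=[0.82, 0.0], state="dna_bound")
        st = _make_state([dim])
        st.config.k_cat = 0.0
        update_bindings(st, st.config.dt, rng)
        assert dim.state == "pc_bound"
        assert dim.next_event_time == math.inf

    def test_release_dwell_matches_exponential_mean(self, rng):
        """1e4 scheduled dwells at k_cat = 0.03: mean 33.3 s within 3 SE."""
        k_cat = 0.03
        dwells = []
        for _ in range(100):
            dims = [ParADimer(position=[0.8, 0.0], eq_point=[0.8, 0.0], state="dna_bound")
                    for _ in range(100)]
            st = _make_state(dims, k_cat=k_cat)
            update_bindings(st, st.config.dt, rng)
            dwells.extend(d.next_event_time - st.t for d in dims)
        dwells = np.asarray(dwells)
        mean = 1 / k_cat
        assert len(dwells) == 10_000
        assert abs(dwells.mean() - mean) < 3 * mean / math.sqrt(len(dwells))

    def test_rebinding_sets_fresh_anchor(self, rng):
        dim = ParADimer(position=[1.4, 0.1], eq_point=None, state="free",
                        next_event_time=0.0)
        st = _make_state([dim])
        update_bindings(st, st.config.dt, rng)
        assert dim.state == "dna_bound"
        assert np.allclose(dim.position, dim.eq_point)
        assert dim.position[0] > st.complex.position[0]

    def test_attached_dimers_inherit_complex_displacement(self, rng):
        dim = ParADimer(position=[0.82, 0.0], eq_point=[0.82, 0.0], state="pc_bound",
                        next_event_time=math.inf)
        st = _make_state([dim])
        st.complex.bound_ids = {0}
        st.last_displacement = np.array([0.005, -0.002])
        update_bindings(st, st.config.dt, rng)
        assert np.allclose(dim.position, [0.825, -0.002])

    def test_inconsistent_bookkeeping_raises(self, rng):
        dim = ParADimer(position=[0.8, 0.0], eq_point=None, state="free",
                        next_event_time=math.inf)
        st = _make_state([dim])
        st.complex.bound_ids = {0}
        with pytest.raises(InternalConsistencyError):
            update_bindings(st, st.config.dt, rng)

    def test_noop_for_pure_diffusion_model(self, rng):
        dim = ParADimer(position=[0.81, 0.0], eq_point=[0.81, 0.0], state="dna_bound")
        st = _make_state([dim], model="diffusion")
        update_bindings(st, st.config.dt, rng)
        assert dim.state == "dna_bound"
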