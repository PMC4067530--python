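"""Brownian-dynamics engine for partition-complex translocation.

Implements three candidate mechanisms for ParABS-mediated segregation in a
2-D reflective cell:

``diffusion``
    The partition complex diffuses freely (null model).
``diffusion_binding``
    The complex additionally binds/unbinds immobile DNA-bound ParA-ATP
    dimers; a rigid bond to an immobile tether transiently stalls the
    complex but exerts no directed force (Brownian-ratchet null model).
``dna_relay``
    DNA-bound dimers fluctuate in harmonic wells (the elasticity of the
    chromosomal loci they are bound to); a dimer captured in a stretched
    state pulls the complex toward its tether anchor, relaying it down the
    ParA gradient.

The public operations (:func:`sample_correlated_noise`, :func:`spring_force`,
:func:`bd_step`, :func:`reflect`, :func:`sample_rebinding_x`,
:func:`update_bindings`) are plain NumPy implementations of the individual
model ingredients; :func:`run_model`/:func:`run_ensemble` execute whole
trajectories through the compiled kernel in :mod:`dnarelay._kernels`, which
applies the algebraically identical update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .config import SimulationConfig

__all__ = [
    "ParADimer",
    "PartitionComplex",
    "SimState",
    "RunResult",
    "EnsembleResult",
    "sample_correlated_noise",
    "spring_force",
    "bd_step",
    "reflect",
    "sample_rebinding_x",
    "update_bindings",
    "run_model",
    "run_ensemble",
    "derive_run_seed",
]

_MODEL_IDS = {"diffusion": 0, "diffusion_binding": 1, "dna_relay": 2}

DIMER_STATES = ("dna_bound", "pc_bound", "free")


class InvalidStateError(ValueError):
    """A stochastic operation was asked for from an impossible state."""


class InternalConsistencyError(RuntimeError):
    """Agent bookkeeping violated an invariant of the state machine."""


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------


@dataclass
class ParADimer:
    """A ParA-ATP dimer: position, tether anchor and kinetic state."""

    position: np.ndarray
    eq_point: np.ndarray | None
    state: str
    next_event_time: float = math.inf

    def __post_init__(self) -> None:
        if self.state not in DIMER_STATES:
            raise ValueError(f"state must be one of {DIMER_STATES}")
        self.position = np.asarray(self.position, dtype=float)
        if self.eq_point is not None:
            self.eq_point = np.asarray(self.eq_point, dtype=float)


@dataclass
class PartitionComplex:
    """The ParB/parS partition complex and its current attachments."""

    position: np.ndarray
    bound_ids: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class SimState:
    """Explicit simulation state used by the step-wise Python operations."""

    config: SimulationConfig
    complex: PartitionComplex
    dimers: list[ParADimer]
    t: float = 0.0
    #: displacement of the complex over the last position update (um).
    last_displacement: np.ndarray = field(default_factory=lambda: np.zeros(2))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def sample_correlated_noise(D, dt, rng, size=None):
    """Draw the correlated Gaussian pair (R0, R1) of the second-order scheme.

    R0 (um) is the free-diffusion displacement, Var(R0) = 2 D dt; R1 (um*s)
    enters the force-gradient term, Var(R1) = (2/3) D dt^3, and the pair is
    correlated with Cov(R0, R1) = D dt^2.  Sampled via the conditional law
    R1 | R0 = (dt/2) R0 + sqrt(D dt^3 / 6) Z.
    """
    if not D > 0:
        raise ValueError("diffusion coefficient D must be positive")
    if not dt > 0:
        raise ValueError("time step dt must be positive")
    r0 = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=size)
    r1 = 0.5 * dt * r0 + rng.normal(0.0, math.sqrt(D * dt**3 / 6.0), size=size)
    return r0, r1


def spring_force(position, eq_point, k_over_kT, kT=1.0):
    """Harmonic restoring force of a tether, per axis.

    ``k_over_kT`` is 1/sigma^2 per axis (um^-2).  Returns ``(force,
    force_deriv)`` with ``force = -k (x - x_eq)`` and ``force_deriv = -k``
    where ``k = k_over_kT * kT``: the force opposes the displacement and
    drives the particle back toward the anchor.  With ``kT = 1`` the result
    is in reduced units F/kT (um^-1), which is all the integrator needs.
    """
    position = np.asarray(position, dtype=float)
    eq_point = np.asarray(eq_point, dtype=float)
    k = np.asarray(k_over_kT, dtype=float) * kT
    force = -k * (position - eq_point)
    deriv = np.broadcast_to(-k, force.shape).copy()
    return force, deriv


def bd_step(position, force, force_deriv, D, dt, rng, kT=1.0):
    """Advance positions by one second-order overdamped step (per axis).

    x' = x + R0 + (D/kT) F dt + (D^2/2(kT)^2) F F' dt^2 + (D/kT) F' R1,
    with fresh correlated noise per component.  With F = F' = 0 this is a
    pure diffusion increment.
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    force_deriv = np.asarray(force_deriv, dtype=float)
    shape = position.shape if position.shape else None
    r0, r1 = sample_correlated_noise(D, dt, rng, size=shape)
    mobility = D / kT
    return (
        position
        + r0
        + mobility * force * dt
        + 0.5 * mobility**2 * force * force_deriv * dt**2
        + mobility * force_deriv * r1
    )


def _fold(values, lo, hi):
    period = 2.0 * (hi - lo)
    v = np.mod(np.asarray(values, dtype=float) - lo, period)
    v = np.where(v > hi - lo, period - v, v)
    return v + lo


def reflect(position, l0, w0):
    """Mirror-reflect a coordinate pair into the cell [0, l0] x [-w0/2, w0/2].

    Idempotent for interior points; arbitrarily large overshoots fold back
    by repeated mirroring.
    """
    position = np.asarray(position, dtype=float)
    x = _fold(position[..., 0], 0.0, l0)
    y = _fold(position[..., 1], -w0 / 2.0, w0 / 2.0)
    return np.stack([x, y], axis=-1)


def sample_rebinding_x(x_pc, l, rng, size=None):
    """Sample a ParA rebinding coordinate from the linear density.

    P(x) = 2 (x - x_pc) / (l - x_pc)^2 on (x_pc, l): rebinding is biased
    toward the new pole, emulating the intracellular ParA gradient ahead of
    the partition complex.  Inverse CDF: x = x_pc + (l - x_pc) sqrt(u).
    """
    if x_pc >= l:
        raise InvalidStateError(
            f"complex position x_pc={x_pc} at/after the new pole (l={l}): "
            "no rebinding region"
        )
    u = rng.random(size) if size is not None else rng.random()
    return x_pc + (l - x_pc) * np.sqrt(u)


# ---------------------------------------------------------------------------
# state machine
# ---------------------------------------------------------------------------


def update_bindings(state: SimState, dt: float, rng) -> SimState:
    """Advance the binding state machine of a :class:`SimState` by ``dt``.

    In order: pc-bound dimers inherit the complex's last displacement;
    DNA-bound dimers overlapping the complex disk are captured (immediate
    and deterministic, boundary contact counts); pc-bound dimers whose
    scheduled hydrolysis time has passed are released (exponential dwell,
    mean 1/k_cat, drawn at capture); free dimers whose rebinding time has
    passed rebind ahead of the complex (exponential wait, mean tau_db).
    A no-op for the pure-diffusion model.
    """
    cfg = state.config
    state.t += dt
    if cfg.model == "diffusion":
        return state

    for i, dim in enumerate(state.dimers):
        if dim.state == "free" and i in state.complex.bound_ids:
            raise InternalConsistencyError(
                f"free dimer {i} present in partition-complex bookkeeping"
            )

    capture_radius = cfg.R_PC + cfg.R_ParA
    pos_pc = state.complex.position

    # attached dimers ride with the complex
    for i in state.complex.bound_ids:
        state.dimers[i].position = state.dimers[i].position + state.last_displacement

    for i, dim in enumerate(state.dimers):
        if dim.state == "dna_bound":
            if np.hypot(*(dim.position - pos_pc)) <= capture_radius:
                dim.state = "pc_bound"
                dwell = math.inf if cfg.k_cat == 0 else rng.exponential(1.0 / cfg.k_cat)
                dim.next_event_time = state.t + dwell
                state.complex.bound_ids.add(i)
        elif dim.state == "pc_bound":
            if state.t >= dim.next_event_time:
                dim.state = "free"
                dim.eq_point = None
                dim.next_event_time = state.t + rng.exponential(cfg.tau_db)
                state.complex.bound_ids.discard(i)
        else:  # free
            if state.t >= dim.next_event_time and pos_pc[0] < cfg.l0:
                x = sample_rebinding_x(pos_pc[0], cfg.l0, rng)
                y = rng.uniform(-cfg.w0 / 2.0, cfg.w0 / 2.0)
                dim.position = np.array([x, y])
                dim.eq_point = dim.position.copy()
                dim.state = "dna_bound"
                dim.next_event_time = math.inf
    return state


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """One recorded trajectory of the partition complex."""

    frame: pd.DataFrame          # columns t_s, x_um, y_um, n_bound
    crossing_time: float | None  # s, None if x_finish was never reached
    dimers: list[ParADimer]
    config: SimulationConfig
    run_index: int
    seed: int

    @property
    def completed(self) -> bool:
        return self.crossing_time is not None


@dataclass
class EnsembleResult:
    """Ensemble summary: mean trajectory and completion statistics.

    Runs that finish early are held at ``x_finish`` for averaging, so the
    completion fraction is non-decreasing by construction.
    """

    times: np.ndarray
    mean_position: np.ndarray
    completion_fraction: np.ndarray
    per_run_crossing_time: np.ndarray  # s, NaN where the run never crossed
    config: SimulationConfig

    @property
    def n_runs(self) -> int:
        return len(self.per_run_crossing_time)

    @property
    def final_completion_fraction(self) -> float:
        return float(self.completion_fraction[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "mean_x_um": self.mean_position,
                "completion_fraction": self.completion_fraction,
            }
        )


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Per-run kernel seed: child ``run_index`` of SeedSequence(master)."""
    return int(np.random.SeedSequence((master_seed, run_index)).generate_state(1)[0] % 2**31)


def run_model(config: SimulationConfig, run_index: int = 0) -> RunResult:
    """Run one trajectory under ``config``; deterministic in (seed, config).

    The complex starts at (x0, y0); ParA dimers start DNA-bound with anchors
    drawn from the rebinding density around the initial complex position.
    The run ends at ``t_fin`` or at the first crossing of ``x_finish``.
    """
    config.validate()
    seed = derive_run_seed(config.seed, run_index)
    n_steps = int(round(config.t_fin / config.dt))
    out = _kernels.simulate_run(
        seed,
        _MODEL_IDS[config.model],
        n_steps,
        config.dt,
        config.l0,
        config.w0,
        config.x0,
        config.y0,
        config.x_finish,
        config.R_PC + config.R_ParA,
        config.n_ParA if config.model != "diffusion" else 0,
        config.k_cat,
        config.tau_db,
        config.D_PC,
        config.D_A,
        1.0 / config.sigma_long**2,
        1.0 / config.sigma_short**2,
        config.record_every,
        config.active_window,
    )
    (n_rec, t_rec, x_rec, y_rec, nb_rec, ndna_rec, nfree_rec, crossing,
     dim_x, dim_y, dim_ex, dim_ey, dim_state, dim_tev) = out

    frame = pd.DataFrame(
        {
            "t_s": t_rec[:n_rec],
            "x_um": x_rec[:n_rec],
            "y_um": y_rec[:n_rec],
            "n_bound": nb_rec[:n_rec],
        }
    )
    if config.model != "diffusion":
        total = ndna_rec[:n_rec] + nb_rec[:n_rec] + nfree_rec[:n_rec]
        if not np.all(total == config.n_ParA):
            raise InternalConsistencyError("ParA state populations not conserved")

    state_names = {0: "dna_bound", 1: "pc_bound", 2: "free"}
    dimers = []
    if config.model != "diffusion":
        for i in range(config.n_ParA):
            st = state_names[int(dim_state[i])]
            dimers.append(
                ParADimer(
                    position=np.array([dim_x[i], dim_y[i]]),
                    eq_point=None if st == "free" else np.array([dim_ex[i], dim_ey[i]]),
                    state=st,
                    next_event_time=float(dim_tev[i]),
                )
            )
    return RunResult(
        frame=frame,
        crossing_time=float(crossing) if crossing >= 0 else None,
        dimers=dimers,
        config=config,
        run_index=run_index,
        seed=seed,
    )


def run_ensemble(config: SimulationConfig, keep_runs: bool = False):
    """Run ``config.n_runs`` independent trajectories and summarise them.

    Per-run RNG substreams are children of the master seed (documented in
    :func:`derive_run_seed`).  Returns an :class:`EnsembleResult`; with
    ``keep_runs=True`` returns ``(ensemble, [RunResult, ...])``.
    """
    config.validate()
    n_steps = int(round(config.t_fin / config.dt))
    n_grid = n_steps // config.record_every + 1
    times = np.arange(n_grid) * (config.record_every * config.dt)

    positions = np.empty((config.n_runs, n_grid))
    crossings = np.full(config.n_runs, np.nan)
    runs: list[RunResult] = []
    for r in range(config.n_runs):
        res = run_model(config, run_index=r)
        x = res.frame["x_um"].to_numpy()
        positions[r, : len(x)] = x
        if res.crossing_time is not None:
            # early-finished runs hold the target position
            positions[r, len(x):] = config.x_finish
            crossings[r] = res.crossing_time
        else:
            positions[r, len(x):] = x[-1] if len(x) else config.x0
        if keep_runs:
            runs.append(res)

    with np.errstate(invalid="ignore"):
        completion = np.mean(
            (crossings[:, None] <= times[None, :]) & np.isfinite(crossings[:, None]),
            axis=0,
        )
    ens = EnsembleResult(
        times=times,
        mean_position=positions.mean(axis=0),
        completion_fraction=completion,
        per_run_crossing_time=crossings,
        config=config,
    )
    return (ens, runs) if keep_runs else ens
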