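"""Simulation configuration: defaults, validation and file loading.

The defaults are the measured cellular parameters of the *Caulobacter
crescentus* ParABS system: a 2.5 x 0.4 um reflective cell, 90 DNA-bound
ParA-ATP dimers, a 50-nm partition-complex disk, a ParB-stimulated hydrolysis
rate of 0.03 1/s, and locus-fluctuation amplitudes sigma_long = 0.06 um /
sigma_short = 0.04 um defining the elastic constants via k_sp/kT = 1/sigma^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .constants import DEFAULT_TEMPERATURE_K

#: Supported translocation mechanisms.
MODELS = ("diffusion", "diffusion_binding", "dna_relay")


class ConfigError(ValueError):
    """Raised when a configuration file or value is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of one Brownian-dynamics ensemble.

    Lengths in um, times in s, diffusivities in um^2/s, rates in 1/s.
    ``sigma_long``/``sigma_short`` are the positional-fluctuation SDs of
    DNA-bound ParA tethers along the long/short cell axis; the spring
    constants used by the integrator are ``k_sp/kT = 1/sigma^2``.
    """

    dt: float = 0.001            # integrator time step, s
    t_fin: float = 2000.0        # maximum simulated time, s
    n_runs: int = 1024           # ensemble size
    l0: float = 2.5              # cell (box) length, um; old pole at x=0
    w0: float = 0.4              # cell width, um; walls at +-w0/2
    x0: float = 0.8              # initial complex position along x, um
    y0: float = 0.0              # initial complex position along y, um
    x_start: float = 1.5         # fast-phase analysis window start, um
    x_finish: float = 2.5        # translocation target (absorbing), um
    R_PC: float = 0.05           # partition-complex disk radius, um
    R_ParA: float = 0.002        # ParA-dimer disk radius, um
    n_ParA: int = 90             # number of ParA-ATP dimers
    k_cat: float = 0.03          # ParB-stimulated hydrolysis rate, 1/s
    tau_db: float = 1.0 / 0.03   # mean free -> DNA-bound rebinding time, s
    D_PC: float = 1e-4           # partition-complex diffusivity, um^2/s
    D_A: float = 0.01            # DNA-bound ParA diffusivity, um^2/s
    sigma_long: float = 0.06     # tether fluctuation SD along x, um
    sigma_short: float = 0.04    # tether fluctuation SD along y, um
    model: str = "dna_relay"
    seed: int = 0
    record_every: int = 1000     # output decimation, steps
    temperature: float = DEFAULT_TEMPERATURE_K  # K; only affects reported forces
    active_window: float = 0.5   # um; tether-integration window (see methods)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        positive = (
            "dt", "t_fin", "l0", "w0", "R_PC", "R_ParA", "k_cat", "tau_db",
            "D_PC", "D_A", "sigma_long", "sigma_short", "temperature",
            "active_window",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.n_ParA < 0:
            raise ConfigError("n_ParA must be >= 0")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        if not 0 <= self.x0 <= self.l0:
            raise ConfigError("x0 must lie in [0, l0]")
        if abs(self.y0) > self.w0 / 2:
            raise ConfigError("|y0| must be <= w0/2")
        if not self.x_start < self.x_finish <= self.l0:
            raise ConfigError("need x_start < x_finish <= l0")
        if not self.R_ParA < self.R_PC:
            raise ConfigError("R_ParA must be smaller than R_PC")
        if self.model not in MODELS:
            raise ConfigError(f"model must be one of {MODELS}")
        if not 0 <= self.seed < 2**31:
            raise ConfigError("seed must lie in [0, 2^31)")
        # Harmonic relaxation must be resolved by the step: the fastest
        # tether time scale is min(sigma^2)/D_A.
        tau_relax = min(self.sigma_long, self.sigma_short) ** 2 / self.D_A
        if self.dt > 0.1 * tau_relax:
            raise ConfigError(
                f"dt={self.dt} too coarse for tether relaxation time "
                f"{tau_relax:.4g} s (need dt <= {0.1 * tau_relax:.4g})"
            )

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML/JSON config; unspecified keys fall back to the defaults.

    Unknown keys are a hard error so that a typo never silently reverts a
    parameter to its default.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of parameter names")
    try:
        return SimulationConfig.from_dict(data)
    except ConfigError as err:
        raise ConfigError(f"{path}: {err}") from err
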