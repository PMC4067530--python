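import numpy as np
import pytest
from hypothesis import settings

from dnarelay import SimulationConfig, run_ensemble

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# shared heavy ensembles (scaled-down study conditions; session-scoped so the
# model-contrast and rate-optimum checks reuse the same simulations)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def diffusion_binding_ensemble():
    """50 diffusion-binding runs at the measured parameters.

    The model is forceless, so the integrator step can be coarsened to 5 ms
    without changing the outcome; 2000 s covers the 30-min observation
    window.
    """
    cfg = SimulationConfig(model="diffusion_binding", dt=0.005, t_fin=2000.0,
                           n_runs=50, seed=1101)
    return run_ensemble(cfg)


@pytest.fixture(scope="session")
def relay_kcat_scan():
    """25 DNA-relay runs each at k_cat = 0.003, 0.03, 0.3 1/s (D_PC = 1e-4)."""
    out = {}
    for k_cat in (0.003, 0.03, 0.3):
        cfg = SimulationConfig(model="dna_relay", n_runs=25, k_cat=k_cat,
                               tau_db=1.0 / 0.03, seed=2203)
        out[k_cat] = run_ensemble(cfg)
    return out
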