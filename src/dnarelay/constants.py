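"""Physical constants and small numeric helpers shared across the package.

All mechanics inside the simulator depend only on the ratio ``k_sp/kT``; the
absolute thermal energy enters solely when forces are reported in piconewtons.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: Avogadro constant, 1/mol.
AVOGADRO: float = _sc.Avogadro

#: Boltzmann constant in pN*um/K (1 J = 1e12 pN * 1e6 um = 1e18 pN*um).
BOLTZMANN_PN_UM: float = _sc.Boltzmann * 1e18

#: Default absolute temperature, K (30 C growth/imaging temperature).
DEFAULT_TEMPERATURE_K: float = 303.0


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kT in pN*um at the given absolute temperature."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return BOLTZMANN_PN_UM * temperature_k


def round_sigfigs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures (reporting helper only).

    Never applied internally to quantities that feed further computation.
    """
    if n < 1:
        raise ValueError("need at least one significant figure")
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))
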