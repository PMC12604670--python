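"""Physical constants and unit helpers.

All experimental-side quantities are carried in micrometres, seconds and
piconewtons; thermal energy is therefore expressed in pN·μm.  Simulation-side
quantities use reduced Lennard-Jones units (σ = ε = m = 1).
"""

from __future__ import annotations

import scipy.constants

#: Boltzmann constant in pN·μm per kelvin (1 pN·μm = 1e-18 J).
KB_PN_UM = scipy.constants.Boltzmann / 1e-18

#: Default laboratory temperature (K) used when none is given.
DEFAULT_TEMPERATURE = 298.0


def kbt_pn_um(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in pN·μm at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_UM * temperature
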