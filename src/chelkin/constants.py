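"""Physical constants and unit conventions.

Energies are kJ/mol, concentrations mol/L, times ps (trajectories) or s
(rate constants), distances Angstrom. Conversions happen at module
boundaries only.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (gas constant per mole).
KB_KJ_MOL_K: float = 0.0083145

#: Avogadro's number, mol^-1.
N_AVOGADRO: float = 6.02214076e23

#: Default bath temperature, K.
DEFAULT_TEMPERATURE: float = 300.0

import math as _math


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJ_MOL_K * temperature


LN10: float = _math.log(10.0)
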