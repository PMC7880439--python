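"""Internal unit system and physical constants.

The simulation works in molecular-scale units to keep floating-point numbers
near unity:

========  =========================================
quantity  internal unit
========  =========================================
length    nm
time      µs
energy    kT at the reference temperature 295.15 K
angle     rad
========  =========================================

Stiffnesses supplied "in kT" are interpreted at ``T_REF`` (295.15 K = 22 °C,
the ambient temperature the freezing protocols start from).  At a different
instantaneous temperature T the thermal energy in internal units is simply
``T / T_REF``.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K (exact, SI 2019).
KB_SI = 1.380649e-23

#: Reference temperature for the internal energy unit, K (22 degC).
T_REF = 295.15

#: One internal energy unit, in joules (kB * T_REF).
E_UNIT = KB_SI * T_REF

#: Boltzmann constant in internal units (energy units per kelvin).
KB = 1.0 / T_REF

#: Molar gas constant in kcal / (mol K).
R_KCAL_MOL_K = 1.987204e-3

#: Stokes translational drag prefactor: gamma_t = DRAG_T * R[nm] * eta[Pa s]
#: in internal units (energy * µs / nm^2).  gamma_t = 6 pi R eta.
DRAG_T = 6.0 * math.pi * 1e-9 / (E_UNIT * 1e-6 / 1e-18)

#: Stokes rotational drag prefactor: gamma_r = DRAG_R * R[nm]^3 * eta[Pa s]
#: in internal units (energy * µs).  gamma_r = 8 pi R^3 eta.
DRAG_R = 8.0 * math.pi * 1e-27 / (E_UNIT * 1e-6)


def kcal_per_mol_to_kt(value: float, temperature: float) -> float:
    """Convert an energy from kcal/mol to units of kT at ``temperature`` (K)."""
    return value / (R_KCAL_MOL_K * temperature)


def kt_at(temperature: float) -> float:
    """Thermal energy kB*T at ``temperature`` (K), in internal energy units."""
    return KB * temperature
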