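"""Physical constants (CODATA 2018, exact SI values) and unit conversions.

Internally the package works in reduced units: lengths in nm, areal
densities in nm^-2, volume densities in nm^-3, and electrostatic
potentials as the dimensionless combination x = e*phi/(k_B*T).  SI
quantities appear only in reporting helpers.
"""

from __future__ import annotations

import math

#: Elementary charge (C).
ELEMENTARY_CHARGE = 1.602176634e-19

#: Boltzmann constant (J/K).
BOLTZMANN = 1.380649e-23

#: Avogadro constant (1/mol).
AVOGADRO = 6.02214076e23

#: Number density of a 1 mol/L solution, in nm^-3.
MOLAR_TO_NM3 = AVOGADRO * 1e-24  # = 0.602214076

LN10 = math.log(10.0)


def molar_to_number_density(conc_molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density in nm^-3."""
    return conc_molar * MOLAR_TO_NM3


def number_density_to_molar(rho_nm3: float) -> float:
    """Convert a number density in nm^-3 to a molar concentration (mol/L)."""
    return rho_nm3 / MOLAR_TO_NM3
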