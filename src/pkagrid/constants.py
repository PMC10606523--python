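"""Physical constants and unit conversions used throughout the package.

Internal energy unit is kcal/mol; potentials are stored in kT/e at the run
temperature; pKa-unit energies are kcal/mol divided by ln(10)*R*T
(1.364 kcal/mol at 298 K).
"""

import math

#: e^2 / (4 pi eps0) in kcal * Angstrom / (mol * e^2)
COULOMB_KCAL_A = 332.0637

#: Gas constant in kcal / (mol * K)
R_KCAL = 1.987204e-3

AVOGADRO = 6.02214076e23

DEFAULT_TEMPERATURE = 298.0


def kt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal/mol."""
    return R_KCAL * temperature


def ln10_kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ln(10) * RT in kcal/mol -- one pKa unit of free energy (1.364 at 298 K)."""
    return math.log(10.0) * kt_kcal(temperature)


def eps_kappa_sq(ionic_strength: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Product eps * kappa^2 in 1/A^2 for a 1:1 electrolyte.

    eps*kappa^2 = 8 pi C I N_A 1e-27 / RT with I in mol/L.  The Debye length in
    a medium of permittivity eps is sqrt(eps / (eps*kappa^2)); for water
    (eps 81) at 0.2 M this gives ~6.9 A.
    """
    return 8.0 * math.pi * COULOMB_KCAL_A * AVOGADRO * 1e-27 * ionic_strength / kt_kcal(temperature)
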