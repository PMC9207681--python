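"""Physical constants (CODATA 2018) and closed-form electrolyte lengths.

Internal unit conventions used across the package:

* lengths in angstrom (A)
* charges in elementary charges (e)
* energies in units of kT (with T taken from the solver configuration)
* electrostatic potentials in kT/e unless explicitly converted
"""

from __future__ import annotations

import math

# CODATA 2018 exact / recommended values (SI)
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
VACUUM_PERMITTIVITY_F_PER_M = 8.8541878128e-12
AVOGADRO_PER_MOL = 6.02214076e23

METERS_PER_ANGSTROM = 1e-10


def debye_length(ionic_strength_M: float, temperature_K: float,
                 relative_permittivity: float) -> float:
    """Debye screening length of a monovalent electrolyte, in angstrom.

    lambda = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)), with the ionic
    strength ``I`` given in mol/L.

    Raises
    ------
    ValueError
        If any argument is not strictly positive.
    """
    if ionic_strength_M <= 0:
        raise ValueError(f"ionic strength must be > 0 (got {ionic_strength_M})")
    if temperature_K <= 0:
        raise ValueError(f"temperature must be > 0 (got {temperature_K})")
    if relative_permittivity <= 0:
        raise ValueError(
            f"relative permittivity must be > 0 (got {relative_permittivity})")
    number_density_per_m3 = ionic_strength_M * 1000.0 * AVOGADRO_PER_MOL
    lam_m = math.sqrt(
        VACUUM_PERMITTIVITY_F_PER_M * relative_permittivity
        * BOLTZMANN_J_PER_K * temperature_K
        / (2.0 * number_density_per_m3 * ELEMENTARY_CHARGE_C ** 2))
    return lam_m / METERS_PER_ANGSTROM


def bjerrum_length(temperature_K: float, relative_permittivity: float) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T), in angstrom."""
    if temperature_K <= 0 or relative_permittivity <= 0:
        raise ValueError("temperature and permittivity must be > 0")
    lb_m = ELEMENTARY_CHARGE_C ** 2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY_F_PER_M * relative_permittivity
        * BOLTZMANN_J_PER_K * temperature_K)
    return lb_m / METERS_PER_ANGSTROM


def ion_number_density_per_A3(ionic_strength_M: float) -> float:
    """Bulk number density of one ion species in 1/A^3 for a given molarity."""
    if ionic_strength_M < 0:
        raise ValueError("ionic strength must be >= 0")
    return ionic_strength_M * 1000.0 * AVOGADRO_PER_MOL * 1e-30


def kT_joule(temperature_K: float) -> float:
    return BOLTZMANN_J_PER_K * temperature_K
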