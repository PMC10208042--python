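"""Physical constants and unit conventions.

Internal units: length in angstrom (A), time in femtoseconds (fs), mass in
atomic mass units (amu), energy in kcal/mol, charge in units of the
elementary charge (e).  With these choices velocities are A/fs and forces
kcal/mol/A; kinetic energy computed as (1/2) m v**2 comes out in
amu*A^2/fs^2 and must be converted with :data:`KCAL_PER_INTERNAL`.
"""

import numpy as np

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb constant, kcal A / (mol e^2).
COULOMB = 332.06371

#: 1 amu*A^2/fs^2 expressed in kcal/mol (= 1e7 J/mol / 4184 J/kcal).
KCAL_PER_INTERNAL = 1.0e7 / 4184.0

#: 1 kcal/mol expressed in amu*A^2/fs^2 (acceleration conversion).
INTERNAL_PER_KCAL = 1.0 / KCAL_PER_INTERNAL

#: Standard atomic masses (amu) for the supported element set.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
}

#: Element symbols the machine-learning potential may see.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "S", "F", "Cl")

#: 1 atm expressed in kcal/(mol A^3).
ATM_TO_KCAL_PER_A3 = 1.4583972574e-5


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Kinetic energy in kcal/mol from amu masses and A/fs velocities."""
    ke_internal = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    return ke_internal * KCAL_PER_INTERNAL
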