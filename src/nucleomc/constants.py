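"""Physical constants and the fixed internal unit system.

Internal units throughout the package: lengths in angstrom (Å), energies in
units of kT at the system temperature, angles in degrees, charges in units of
the elementary charge e.  Keeping every energy term in kT makes the Metropolis
exponent dimensionless by construction.
"""

import math

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K

#: Default solvent relative permittivity (water at 298.15 K).
EPS_R_WATER = 78.4
#: Default simulation temperature, K.
T_ROOM = 298.15


def thermal_energy(temperature: float = T_ROOM) -> float:
    """kT in joule."""
    return BOLTZMANN * temperature


def bjerrum_length(eps_r: float = EPS_R_WATER, temperature: float = T_ROOM) -> float:
    """Bjerrum length in Å: the separation at which two unit charges in the
    dielectric continuum interact with energy kT.

    For water at 298.15 K this is 7.15 Å (rounds to the conventional 7 Å).
    """
    if eps_r <= 0 or temperature <= 0:
        raise ValueError("eps_r and temperature must be positive")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature
    )
    return lb_m * 1e10


#: Harmonic bond force constant, 0.4 N/m expressed in kT/Å² at 298.15 K.
K_BOND_DEFAULT = 0.4e-20 / thermal_energy()  # 0.4 J/m² × 1e-20 m²/Å²
#: Angular force constant, 3.4e-24 J/deg² expressed in kT/deg² at 298.15 K.
K_ANG_DEFAULT = 3.4e-24 / thermal_energy()
#: Equilibrium bond length, Å.
R0_DEFAULT = 5.0
#: Equilibrium chain angle, degrees (straight chain).
ALPHA0_DEFAULT = 180.0
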