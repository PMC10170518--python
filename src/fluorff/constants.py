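"""Physical constants and element tables.

Internal unit system: kJ/mol (energy), Angstrom (length), radians (angle),
unified atomic mass units (mass), Kelvin (temperature).  The derived internal
time unit is sqrt(amu * A^2 / (kJ/mol)) = 100 fs exactly, so a femtosecond
time step is 0.01 internal units.
"""

# Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * A / e^2
COULOMB_CONSTANT = 1389.3546

# Boltzmann constant per mole, kJ/mol/K
KB = 8.3144621e-3

# 1 fs expressed in the internal time unit (see module docstring)
FEMTOSECOND = 0.01

# Atomic masses, amu
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
    "Cl": 35.45,
}

# van der Waals radii, Angstrom (Bondi)
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "S": 1.80,
    "Cl": 1.75,
}


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
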