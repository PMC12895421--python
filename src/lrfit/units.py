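"""Unit conversion constants.

All internal computation is done in Hartree atomic units (4*pi*eps0 = 1,
lengths in bohr, energies in hartree) with angles in radians.  Files at the
I/O boundary default to the spectroscopic conventions used throughout the
long-range literature: angstrom, degree, cm^-1.
"""

from __future__ import annotations

import math

#: 1 hartree in cm^-1 (CODATA 2018)
HARTREE_TO_CM1 = 219474.6313632
#: 1 bohr in angstrom (CODATA 2018)
BOHR_TO_ANGSTROM = 0.529177210903

ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
CM1_TO_HARTREE = 1.0 / HARTREE_TO_CM1

DEG_TO_RAD = math.pi / 180.0
RAD_TO_DEG = 180.0 / math.pi

#: distance unit name -> factor converting to bohr
DISTANCE_TO_BOHR = {
    "bohr": 1.0,
    "au": 1.0,
    "angstrom": ANGSTROM_TO_BOHR,
    "A": ANGSTROM_TO_BOHR,
    "nm": 10.0 * ANGSTROM_TO_BOHR,
}

#: energy unit name -> factor converting to hartree
ENERGY_TO_HARTREE = {
    "hartree": 1.0,
    "au": 1.0,
    "cm-1": CM1_TO_HARTREE,
    "cm^-1": CM1_TO_HARTREE,
    "kelvin": 3.1668115634564e-6,
    "ev": 1.0 / 27.211386245988,
    "kcal/mol": 1.0 / 627.509474,
}

#: angle unit name -> factor converting to radian
ANGLE_TO_RAD = {
    "rad": 1.0,
    "radian": 1.0,
    "deg": DEG_TO_RAD,
    "degree": DEG_TO_RAD,
}


def to_internal_distance(value, unit: str):
    return value * DISTANCE_TO_BOHR[_norm(unit, DISTANCE_TO_BOHR)]


def to_internal_energy(value, unit: str):
    return value * ENERGY_TO_HARTREE[_norm(unit, ENERGY_TO_HARTREE)]


def to_internal_angle(value, unit: str):
    return value * ANGLE_TO_RAD[_norm(unit, ANGLE_TO_RAD)]


def _norm(unit: str, table) -> str:
    u = unit.strip()
    if u in table:
        return u
    ul = u.lower()
    if ul in table:
        return ul
    raise ValueError(f"unknown unit {unit!r}; known: {sorted(table)}")
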