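"""Embedded benchmark geometries.

Standard equilibrium geometries (Angstrom internally converted to bohr);
the exact points on the potential surface are repository conventions, not
tied to any external dataset.
"""

from __future__ import annotations

import math

import numpy as np

from .system import MolecularSystem
from .units import ANGSTROM_TO_BOHR


def h2(r: float = 0.74, basis: str = "sto-3g") -> MolecularSystem:
    """Hydrogen molecule along z, bond length in Angstrom."""
    return MolecularSystem(
        atoms=["H", "H"],
        coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]) * ANGSTROM_TO_BOHR,
        basis_name=basis,
    )


def water(basis: str = "sto-3g") -> MolecularSystem:
    """H2O, r(OH) = 0.9572 A, HOH angle 104.52 deg, C2 axis along z."""
    r = 0.9572
    theta = math.radians(104.52) / 2.0
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.0, r * math.sin(theta), -r * math.cos(theta)],
        [0.0, -r * math.sin(theta), -r * math.cos(theta)],
    ]) * ANGSTROM_TO_BOHR
    return MolecularSystem(atoms=["O", "H", "H"], coords=coords, basis_name=basis)


def ammonia(basis: str = "sto-3g") -> MolecularSystem:
    """NH3, r(NH) = 1.0116 A, HNH angle 106.7 deg, C3 axis along z."""
    r = 1.0116
    hnh = math.radians(106.7)
    # half-angle relation between the HNH angle and the angle to the C3 axis
    s = math.sin(hnh / 2.0) / math.sin(math.radians(60.0))
    beta = math.asin(s)  # angle N-H makes with the C3 axis
    rho = r * math.sin(beta)
    z = -r * math.cos(beta)
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        coords.append([rho * math.cos(phi), rho * math.sin(phi), z])
    return MolecularSystem(atoms=["N", "H", "H", "H"],
                           coords=np.array(coords) * ANGSTROM_TO_BOHR,
                           basis_name=basis)


def formaldehyde(basis: str = "sto-3g") -> MolecularSystem:
    """CH2O, r(CO) = 1.208 A, r(CH) = 1.116 A, HCH angle 116.5 deg.

    C at the origin, O on +z, hydrogens in the xz plane.
    """
    rco, rch = 1.208, 1.116
    half = math.radians(116.5) / 2.0
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 0.0, rco],
        [rch * math.sin(half), 0.0, -rch * math.cos(half)],
        [-rch * math.sin(half), 0.0, -rch * math.cos(half)],
    ]) * ANGSTROM_TO_BOHR
    return MolecularSystem(atoms=["C", "O", "H", "H"], coords=coords,
                           basis_name=basis)


def ammonium(basis: str = "sto-3g") -> MolecularSystem:
    """NH4+ tetrahedral cation, r(NH) = 1.024 A, total charge +1."""
    a = 1.024 / math.sqrt(3.0)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [a, a, a],
        [a, -a, -a],
        [-a, a, -a],
        [-a, -a, a],
    ]) * ANGSTROM_TO_BOHR
    return MolecularSystem(atoms=["N", "H", "H", "H", "H"], coords=coords,
                           charge=1, basis_name=basis)


FIXTURES = {
    "h2": h2,
    "water": water,
    "ammonia": ammonia,
    "formaldehyde": formaldehyde,
    "ammonium": ammonium,
}


def fixture(name: str, basis: str = "sto-3g") -> MolecularSystem:
    """Look up a named fixture molecule with the given basis."""
    return FIXTURES[name](basis=basis)
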