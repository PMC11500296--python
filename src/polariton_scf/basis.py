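"""Gaussian basis sets: NWChem-format parsing, normalization, shell layout.

Shells store contracted radial coefficients for *raw* cartesian monomials
``x^lx y^ly z^lz exp(-a r^2)``.  Coefficients are scaled so that the
``(l,0,0)`` cartesian component is normalized; the cartesian-to-spherical
matrices below assume exactly this convention.  Published contraction
coefficients refer to individually normalized primitives, which is undone
here once at load time.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

_ANGMOM = {"S": 0, "P": 1, "D": 2, "F": 3}

# cartesian component orders (lx, ly, lz), matching the c2s matrices below
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

_SQRT3 = math.sqrt(3.0)

# real solid harmonics over raw cartesian monomials, (l,0,0)-normalized
# radial convention; rows ordered m = -l..l
_C2S = {
    0: np.array([[1.0]]),
    1: np.eye(3)[[1, 2, 0]],  # p order (x,y,z) -> m = (-1, 0, +1) = (y, z, x)
    2: np.array(
        [
            #  xx       xy      xz     yy      yz     zz
            [0.0, _SQRT3, 0.0, 0.0, 0.0, 0.0],          # m=-2: sqrt3 * xy
            [0.0, 0.0, 0.0, 0.0, _SQRT3, 0.0],          # m=-1: sqrt3 * yz
            [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],           # m= 0: (2zz-xx-yy)/2
            [0.0, 0.0, _SQRT3, 0.0, 0.0, 0.0],          # m=+1: sqrt3 * xz
            [_SQRT3 / 2, 0.0, 0.0, -_SQRT3 / 2, 0.0, 0.0],  # m=+2
        ]
    ),
}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of the (l,0,0) cartesian primitive with exponent alpha."""
    return (
        (2.0 * alpha / math.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / math.sqrt(_double_factorial(2 * l - 1))
    )


@dataclass
class Shell:
    """One contracted shell on one center."""

    l: int
    center: np.ndarray          # (3,) bohr
    exponents: np.ndarray       # (nprim,)
    coefficients: np.ndarray    # (nprim,), normalized convention (see module doc)
    atom_index: int = -1

    @property
    def n_cartesian(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    @property
    def n_spherical(self) -> int:
        return 2 * self.l + 1


def _normalize_contraction(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Scale published coefficients to the raw-monomial convention."""
    cc = coefs * np.array([primitive_norm(a, l) for a in exps])
    # self-overlap of the (l,0,0) component
    ee = exps[:, None] + exps[None, :]
    s = (
        (math.pi ** 1.5)
        * _double_factorial(2 * l - 1)
        / (2.0 ** l)
        * np.sum(cc[:, None] * cc[None, :] / ee ** (l + 1.5))
    )
    return cc / math.sqrt(s)


def parse_nwchem(text: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse an NWChem-format basis block.

    Returns element -> list of (l, exponents, raw coefficients).  SP shells
    are split into an S and a P shell sharing exponents; multi-column general
    contractions become separate shells sharing exponents.
    """
    shells: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    current: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush():
        if current is None or not rows:
            return
        elem, stype = current
        data = np.array(rows)
        exps = data[:, 0]
        if stype == "SP":
            cols = [("S", data[:, 1]), ("P", data[:, 2])]
        else:
            cols = [(stype, data[:, j]) for j in range(1, data.shape[1])]
        for tname, coefs in cols:
            mask = coefs != 0.0
            shells.setdefault(elem, []).append(
                (_ANGMOM[tname], exps[mask], coefs[mask])
            )

    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line or line.upper().startswith(("BASIS", "END")):
            continue
        parts = line.split()
        if parts[0][0].isalpha():
            flush()
            rows = []
            current = (parts[0].capitalize(), parts[1].upper())
        else:
            rows.append([float(x) for x in parts])
    flush()
    return shells


_KNOWN = {
    "sto-3g": "sto-3g.nwchem",
    "6-31g": "6-31g.nwchem",
    "aug-cc-pvdz": "aug-cc-pvdz.nwchem",
}

_cache: dict[str, dict] = {}


def load_basis(name: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Load a named basis set shipped with the package."""
    key = name.strip().lower()
    if key not in _KNOWN:
        raise KeyError(
            f"unknown basis {name!r}; available: {sorted(_KNOWN)}"
        )
    if key not in _cache:
        ref = importlib.resources.files("polariton_scf.data.basis") / _KNOWN[key]
        _cache[key] = parse_nwchem(ref.read_text())
    return _cache[key]


@dataclass
class BasisSet:
    """A basis laid out over the atoms of a molecule."""

    shells: list[Shell]
    name: str = ""

    @property
    def n_spherical(self) -> int:
        return sum(sh.n_spherical for sh in self.shells)

    @property
    def n_cartesian(self) -> int:
        return sum(sh.n_cartesian for sh in self.shells)

    def cart_to_sph_matrix(self) -> np.ndarray:
        """Block-diagonal (n_cartesian, n_spherical) transformation matrix."""
        T = np.zeros((self.n_cartesian, self.n_spherical))
        ic = isp = 0
        for sh in self.shells:
            blk = _C2S[sh.l]
            T[ic:ic + sh.n_cartesian, isp:isp + sh.n_spherical] = blk.T
            ic += sh.n_cartesian
            isp += sh.n_spherical
        return T


def build_basis(atoms: list[str], coords: np.ndarray, name: str) -> BasisSet:
    """Lay out the named basis over a molecule (coords in bohr)."""
    table = load_basis(name)
    shells: list[Shell] = []
    for ia, (sym, xyz) in enumerate(zip(atoms, coords)):
        key = sym.capitalize()
        if key not in table:
            raise KeyError(f"basis {name!r} has no entry for element {sym!r}")
        for l, exps, coefs in table[key]:
            if l not in CART_COMPONENTS:
                raise NotImplementedError(f"angular momentum l={l} not supported")
            cc = _normalize_contraction(l, exps, coefs)
            shells.append(
                Shell(l=l, center=np.asarray(xyz, float), exponents=exps,
                      coefficients=cc, atom_index=ia)
            )
    return BasisSet(shells=shells, name=name)
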