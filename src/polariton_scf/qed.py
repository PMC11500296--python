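"""Strong-coupling QED Hartree-Fock core quantities.

The wave function is ``U_SC |HF> x |0>`` where ``U_SC`` displaces the cavity
mode by an amount that depends on which *dipole-basis* orbital an electron
occupies, with one coherent-state parameter ``eta_p`` per spatial orbital.
Taking the photon expectation values analytically leaves a purely electronic
energy functional in which the one- and two-electron integrals are *dressed*
by Gaussian factors in differences of the eta parameters:

    h_pq   -> h_pq   * exp(-gamma (eta_p - eta_q)^2)
    g_pqrs -> g_pqrs * exp(-gamma (eta_p - eta_q + eta_r - eta_s)^2)

with ``gamma = lambda^2 / (4 omega)``, plus the cavity term

    (lambda^2 / 2) < ( d.eps - sum_p eta_p E~_pp )^2 >

which couples the residual molecular dipole to the eta displacements (at
``eta_p = d~_pp`` the electronic dipole is fully absorbed, which is the
infinite-coupling limit).  The photonic Hilbert space is never represented
explicitly here; only the exact-diagonalization oracle in
:mod:`polariton_scf.validation` builds a photon-number basis.

The dipole basis diagonalizes the polarization-projected dipole operator
over the AO space and is therefore a fixed (molecule- and
polarization-dependent) orbital set; the state of the optimization is the
orthogonal matrix ``U`` expressing the occupied determinant in that basis,
together with ``eta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .integrals import AOIntegralSet
from .system import CavityConfig


# ----------------------------------------------------------------------
# dipole basis
# ----------------------------------------------------------------------

@dataclass
class DipoleBasis:
    """Orbitals diagonalizing the projected dipole (d . eps).

    ``coeff`` are the dipole-basis orbitals over AOs; ``V`` is the orthogonal
    matrix taking the supplied MOs into them; ``d_tilde_diag`` holds the
    eigenvalues (ascending).
    """

    V: np.ndarray
    d_tilde_diag: np.ndarray
    mo_coeff: np.ndarray
    coeff: np.ndarray


def dipole_orbitals(ao: AOIntegralSet, cavity: CavityConfig):
    """Solve (d.eps)_AO c = e S c; deterministic sign fix; ascending order."""
    eps = cavity.polarization
    # electronic dipole operator is minus the position integrals
    dm = -np.einsum("k,kpq->pq", eps, ao.dipole_e)
    w, c = scipy.linalg.eigh(dm, ao.overlap)
    for j in range(c.shape[1]):
        k = np.argmax(np.abs(c[:, j]))
        if c[k, j] < 0:
            c[:, j] = -c[:, j]
    return c, w


def build_dipole_basis(mo_coeff: np.ndarray, ao: AOIntegralSet,
                       cavity: CavityConfig) -> DipoleBasis:
    """Dipole basis for the current MOs (must be S-orthonormal)."""
    S = ao.overlap
    ortho = mo_coeff.T @ S @ mo_coeff
    if not np.allclose(ortho, np.eye(mo_coeff.shape[1]), atol=1e-8):
        raise ValueError("mo_coeff is not orthonormal w.r.t. the AO overlap")
    coeff, w = dipole_orbitals(ao, cavity)
    V = mo_coeff.T @ S @ coeff
    return DipoleBasis(V=V, d_tilde_diag=w, mo_coeff=mo_coeff, coeff=coeff)


# ----------------------------------------------------------------------
# fixed per-molecule/cavity data
# ----------------------------------------------------------------------

class QEDCore:
    """Dipole-basis integrals and cavity constants for one calculation."""

    def __init__(self, ao: AOIntegralSet, cavity: CavityConfig,
                 n_electrons: int):
        if n_electrons % 2:
            raise ValueError("closed-shell reference requires even electrons")
        self.ao = ao
        self.cavity = cavity
        self.n_occ = n_electrons // 2
        self.n = ao.n_basis
        coeff, d_diag = dipole_orbitals(ao, cavity)
        self.coeff = coeff                   # AO x dipole-basis orbitals
        self.d_diag = d_diag                 # eigenvalues of (d.eps)
        self.h = coeff.T @ ao.core_h @ coeff
        g = np.einsum("pi,pqrs->iqrs", coeff, ao.eri, optimize=True)
        g = np.einsum("qj,iqrs->ijrs", coeff, g, optimize=True)
        g = np.einsum("rk,ijrs->ijks", coeff, g, optimize=True)
        self.g = np.einsum("sl,ijks->ijkl", coeff, g, optimize=True)
        self.d_n = float(cavity.polarization @ ao.d_nuc)
        self.e_nuc = ao.e_nuc
        lam, omega = cavity.lambda_coupling, cavity.omega
        if omega <= 0:
            raise ValueError("cavity frequency must be positive")
        self.lam = lam
        self.omega = omega
        self.gamma = lam * lam / (4.0 * omega)

    # -- state helpers -------------------------------------------------
    def density(self, U: np.ndarray) -> np.ndarray:
        """Closed-shell density in the dipole basis from orbital matrix U."""
        Uo = U[:, :self.n_occ]
        return 2.0 * Uo @ Uo.T

    def mo_coeff(self, U: np.ndarray) -> np.ndarray:
        """Canonical MOs over AOs."""
        return self.coeff @ U


# ----------------------------------------------------------------------
# dressed integrals
# ----------------------------------------------------------------------

class DressedIntegrals:
    """Integrals dressed by the Gaussian coherent-state factors for one eta.

    ``h_eta`` and ``g_eta`` are the dressed one- and two-electron integrals;
    additional eta-weighted tensors used by gradients and Hessians are cached
    lazily.  All factors lie in (0, 1] and reduce to 1 at zero coupling or
    equal eta.
    """

    def __init__(self, core: QEDCore, eta: np.ndarray):
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (core.n,):
            raise ValueError("eta length must equal the orbital count")
        self.core = core
        self.eta = eta
        g = core.gamma
        dm = eta[:, None] - eta[None, :]
        self.dm = dm
        self.W1 = np.exp(-g * dm * dm)
        self.h_eta = core.h * self.W1
        S4 = dm[:, :, None, None] + dm[None, None, :, :]
        self.g_eta = core.g * np.exp(-g * S4 * S4)
        self._S4 = S4
        self._cache: dict[str, np.ndarray] = {}

    @property
    def gaussian_exponent_scale(self) -> float:
        return self.core.gamma

    @property
    def S4(self) -> np.ndarray:
        """eta_p - eta_q + eta_r - eta_s."""
        return self._S4

    @property
    def ST2(self) -> np.ndarray:
        """S4 * g_eta (weight for first eta derivatives)."""
        if "ST2" not in self._cache:
            self._cache["ST2"] = self._S4 * self.g_eta
        return self._cache["ST2"]

    @property
    def P4(self) -> np.ndarray:
        """(1 - 2 gamma S4^2) * g_eta (weight for second eta derivatives)."""
        if "P4" not in self._cache:
            g = self.core.gamma
            self._cache["P4"] = (1.0 - 2.0 * g * self._S4 ** 2) * self.g_eta
        return self._cache["P4"]

    @property
    def R1(self) -> np.ndarray:
        """(1 - 2 gamma dm^2) * h_eta."""
        if "R1" not in self._cache:
            g = self.core.gamma
            self._cache["R1"] = (1.0 - 2.0 * g * self.dm ** 2) * self.h_eta
        return self._cache["R1"]

    @property
    def v(self) -> np.ndarray:
        """Residual dipole eigenvalue after eta absorption, d~_pp - eta_p."""
        return self.core.d_diag - self.eta

    # BLAS-friendly Coulomb/exchange builds over the dressed integrals
    def coulomb(self, D: np.ndarray) -> np.ndarray:
        n = self.core.n
        if "gJ" not in self._cache:
            self._cache["gJ"] = self.g_eta.reshape(n * n, n * n)
        return (self._cache["gJ"] @ D.ravel()).reshape(n, n)

    def exchange(self, D: np.ndarray) -> np.ndarray:
        n = self.core.n
        if "gK" not in self._cache:
            self._cache["gK"] = np.ascontiguousarray(
                self.g_eta.transpose(0, 3, 1, 2)).reshape(n * n, n * n)
        return (self._cache["gK"] @ D.ravel()).reshape(n, n)


def dress_integrals(core: QEDCore, eta: np.ndarray) -> DressedIntegrals:
    """Dress the dipole-basis integrals with the Gaussian eta factors."""
    return DressedIntegrals(core, eta)


# ----------------------------------------------------------------------
# energy, Fock matrix, gradients
# ----------------------------------------------------------------------

def _coulomb_exchange(dressed: "DressedIntegrals", D: np.ndarray):
    return dressed.coulomb(D), dressed.exchange(D)


def scqed_energy(core: QEDCore, dressed: DressedIntegrals,
                 D: np.ndarray) -> float:
    """Total SC-QED-HF energy for density D (dipole basis) and dressed eta."""
    lam2 = core.lam ** 2
    v = dressed.v
    J, K = _coulomb_exchange(dressed, D)
    e1 = float(np.sum(dressed.h_eta * D))
    e2 = 0.5 * float(np.sum(J * D)) - 0.25 * float(np.sum(K * D))
    dd = np.diag(D)
    expval = float(v @ dd) + core.d_n          # <d.eps - sum eta E_pp>
    ecav = 0.5 * lam2 * (
        expval ** 2
        - 0.5 * float(v @ (D * D) @ v)
        + float((v * v) @ dd)
    )
    return e1 + e2 + ecav + core.e_nuc


def fock_dipole_basis(core: QEDCore, dressed: DressedIntegrals,
                      D: np.ndarray) -> np.ndarray:
    """SC-QED Fock matrix F~_pq = dE/dD~_pq in the dipole basis."""
    lam2 = core.lam ** 2
    v = dressed.v
    J, K = _coulomb_exchange(dressed, D)
    F = dressed.h_eta + J - 0.5 * K
    expval = float(v @ np.diag(D)) + core.d_n
    F = F - 0.5 * lam2 * np.outer(v, v) * D
    F[np.diag_indices_from(F)] += lam2 * (v * expval + 0.5 * v * v)
    return F


def cavity_response_fock(core: QEDCore, dressed: DressedIntegrals,
                         dD: np.ndarray) -> np.ndarray:
    """Part of F~ linear in the density, applied to a density variation."""
    lam2 = core.lam ** 2
    v = dressed.v
    J, K = _coulomb_exchange(dressed, dD)
    G = J - 0.5 * K - 0.5 * lam2 * np.outer(v, v) * dD
    G[np.diag_indices_from(G)] += lam2 * v * float(v @ np.diag(dD))
    return G


def kappa_gradient(core: QEDCore, dressed: DressedIntegrals,
                   U: np.ndarray) -> np.ndarray:
    """Orbital-rotation gradient dE/dkappa_ai at kappa=0, shape (nv, no).

    The convention is U -> U exp(kappa) with kappa antisymmetric and the
    virtual-occupied block free; in the canonical MO frame the gradient is
    four times the vo block of the Fock matrix.
    """
    D = core.density(U)
    F = fock_dipole_basis(core, dressed, D)
    Fmo = U.T @ F @ U
    no = core.n_occ
    return 4.0 * Fmo[no:, :no]


def eta_gradient(core: QEDCore, dressed: DressedIntegrals,
                 D: np.ndarray) -> np.ndarray:
    """Gradient of the energy with respect to the eta parameters."""
    g = core.gamma
    lam2 = core.lam ** 2
    v = dressed.v
    # one-electron dressing derivative
    one = -4.0 * g * np.einsum("tq,tq,tq->t", dressed.dm, dressed.h_eta, D,
                               optimize=True)
    # two-electron dressing derivative
    G4 = dressed.ST2
    ta = np.einsum("tqrs,tq,rs->t", G4, D, D, optimize=True)
    tb = np.einsum("tqrs,ts,rq->t", G4, D, D, optimize=True)
    two = -4.0 * g * (ta - 0.5 * tb)
    # cavity term: A_pq = D_pp D_qq - D_pq^2 / 2
    dd = np.diag(D)
    Av = dd * (v @ dd) - 0.5 * (D * D) @ v
    cav = -lam2 * (Av + v * dd + core.d_n * dd)
    return one + two + cav


@dataclass
class SCQEDState:
    """Current (or converged) SC-QED-HF state."""

    core: QEDCore
    U: np.ndarray                  # dipole-basis -> canonical-MO orthogonal
    eta: np.ndarray
    energy: float = np.nan
    dipole_basis: DipoleBasis | None = None
    density_tilde: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.density_tilde is None:
            self.density_tilde = self.core.density(self.U)

    @property
    def mo_coeff(self) -> np.ndarray:
        return self.core.mo_coeff(self.U)

    def refresh(self):
        self.density_tilde = self.core.density(self.U)


def apply_kappa(U: np.ndarray, dkappa: np.ndarray, n_occ: int) -> np.ndarray:
    """Rotate orbitals by the exponential map, U exp(kappa)."""
    n = U.shape[0]
    X = np.zeros((n, n))
    X[n_occ:, :n_occ] = dkappa
    X[:n_occ, n_occ:] = -dkappa.T
    return U @ scipy.linalg.expm(X)
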