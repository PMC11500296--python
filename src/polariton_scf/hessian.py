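"""Electronic-photonic Hessian machinery.

The Hessian over the joint parameter vector (kappa, eta) has four blocks.
Only matrix-free linear transformations (Hessian-vector products) are ever
needed by the trust-region solver; they are expressed through gradient-like
contractions of transformed integrals, never through explicit rank-4 Hessian
tensors.  A dense eta-eta block is additionally available for the direct
inversion algorithm; it reuses the already dressed integrals so that no
integral recomputation is involved.

The orbital blocks are evaluated at kappa = 0 in the current MO frame (the
exponential parametrization U -> U exp(kappa)); the eta derivatives are taken
at the current eta.  Neglecting the mixed kappa-eta blocks is the default:
the two parameter classes are only weakly coupled and the kk+ee restriction
is the faster, robust choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qed import (DressedIntegrals, QEDCore, cavity_response_fock,
                  fock_dipole_basis)

KAPPA_KAPPA = "kk"
ETA_ETA = "ee"
MIXED = "mixed"


def _antisym_from_vo(dkappa: np.ndarray, n: int, n_occ: int) -> np.ndarray:
    X = np.zeros((n, n))
    X[n_occ:, :n_occ] = dkappa
    X[:n_occ, n_occ:] = -dkappa.T
    return X


def lt_kappa_kappa(core: QEDCore, dressed: DressedIntegrals, U: np.ndarray,
                   trial_kappa: np.ndarray,
                   Fmo: np.ndarray | None = None) -> np.ndarray:
    """kappa-kappa Hessian times a trial rotation, shape (nv, no).

    Built from the gradient expression: a one-index-transformed Fock term
    plus the response Fock of the rotated density.
    """
    n, no = core.n, core.n_occ
    if trial_kappa.shape != (n - no, no):
        raise ValueError("trial vector must have shape (n_virt, n_occ)")
    D0 = np.zeros((n, n))
    D0[:no, :no] = 2.0 * np.eye(no)
    X = _antisym_from_vo(trial_kappa, n, no)
    if Fmo is None:
        F = fock_dipole_basis(core, dressed, core.density(U))
        Fmo = U.T @ F @ U
    B1 = X @ D0 - D0 @ X                      # density response, MO frame
    dD = U @ B1 @ U.T                         # ... in the dipole basis
    Gmo = U.T @ cavity_response_fock(core, dressed, dD) @ U
    Z = B1 @ Fmo - Fmo @ B1
    A2 = Fmo @ X - X @ Fmo
    return Z[:no, no:].T + 2.0 * A2[no:, :no] + 4.0 * Gmo[no:, :no]


def lt_eta_eta(core: QEDCore, dressed: DressedIntegrals, D: np.ndarray,
               trial_eta: np.ndarray) -> np.ndarray:
    """eta-eta Hessian times a trial vector, via eta-weighted contractions."""
    x = np.asarray(trial_eta, float)
    if x.shape != (core.n,):
        raise ValueError("trial vector length must equal the orbital count")
    g = core.gamma
    lam2 = core.lam ** 2
    dx = x[:, None] - x[None, :]
    # one-electron part
    out = -4.0 * g * np.einsum("tq,tq,tq->t", dx, dressed.R1, D,
                               optimize=True)
    # two-electron part: contract (x_t - x_q + x_r - x_s) against P4 * d~
    P = dressed.P4
    dxD = dx * D
    xa = np.einsum("tqrs,tq,rs->t", P, dxD, D, optimize=True)
    xb = np.einsum("tqrs,rs,tq->t", P, dxD, D, optimize=True)
    Pbra = P * dx[:, :, None, None]
    Pket = P * dx[None, None, :, :]
    xc = np.einsum("tqrs,ts,rq->t", Pbra, D, D, optimize=True)
    xd = np.einsum("tqrs,ts,rq->t", Pket, D, D, optimize=True)
    out += -4.0 * g * (xa + xb - 0.5 * (xc + xd))
    # cavity part: lam^2 (A + diag(D)) x with A_pq = D_pp D_qq - D_pq^2/2
    dd = np.diag(D)
    out += lam2 * (dd * (x @ dd) - 0.5 * (D * D) @ x + dd * x)
    return out


def lt_mixed(core: QEDCore, dressed: DressedIntegrals, U: np.ndarray,
             trial_kappa: np.ndarray, trial_eta: np.ndarray):
    """Mixed-block contributions (kappa<-eta and eta<-kappa).

    Returns (dkappa_out, deta_out): the kappa-eta block applied to the eta
    trial and the eta-kappa block applied to the kappa trial.
    """
    n, no = core.n, core.n_occ
    g = core.gamma
    lam2 = core.lam ** 2
    D = core.density(U)
    v = dressed.v
    dd = np.diag(D)
    x = np.asarray(trial_eta, float)

    # --- kappa output: directional derivative of F~ w.r.t. eta along x ---
    dxm = x[:, None] - x[None, :]
    dh = -2.0 * g * dressed.dm * dxm * dressed.h_eta
    xS = dxm[:, :, None, None] + dxm[None, None, :, :]
    dT = -2.0 * g * (dressed.ST2 * xS)
    dJ = np.einsum("pqrs,rs->pq", dT, D, optimize=True)
    dK = np.einsum("pqrs,qr->ps", dT, D, optimize=True)
    dF = dh + dJ - 0.5 * dK
    # cavity: v' = -x
    expval = float(v @ dd) + core.d_n
    dF = dF + 0.5 * lam2 * (np.outer(x, v) + np.outer(v, x)) * D
    dF[np.diag_indices_from(dF)] += lam2 * (
        -x * (expval + v) + v * float(-x @ dd)
    )
    dFmo = U.T @ dF @ U
    kappa_out = 4.0 * dFmo[no:, :no]

    # --- eta output: derivative of g_eta w.r.t. the density along dD ---
    X = _antisym_from_vo(trial_kappa, n, no)
    D0 = np.zeros((n, n))
    D0[:no, :no] = 2.0 * np.eye(no)
    dD = U @ (X @ D0 - D0 @ X) @ U.T
    one = -4.0 * g * np.einsum("tq,tq,tq->t", dressed.dm, dressed.h_eta, dD,
                               optimize=True)
    G4 = dressed.ST2
    ta = np.einsum("tqrs,tq,rs->t", G4, dD, D, optimize=True)
    tb = np.einsum("tqrs,tq,rs->t", G4, D, dD, optimize=True)
    tc = np.einsum("tqrs,ts,rq->t", G4, dD, D, optimize=True)
    td = np.einsum("tqrs,ts,rq->t", G4, D, dD, optimize=True)
    two = -4.0 * g * (ta + tb - 0.5 * (tc + td))
    ddd = np.diag(dD)
    dAv = ddd * (v @ dd) + dd * (v @ ddd) - (D * dD) @ v
    cav = -lam2 * (dAv + v * ddd + core.d_n * ddd)
    eta_out = one + two + cav
    return kappa_out, eta_out


@dataclass
class DenseEtaEtaHessian:
    """Explicit eta-eta Hessian block (N x N, symmetric)."""

    matrix: np.ndarray
    build_cost_note: str = "N^4 contraction of dressed two-electron integrals"


def build_dense_eta_eta(core: QEDCore, dressed: DressedIntegrals,
                        D: np.ndarray) -> DenseEtaEtaHessian:
    """Assemble the dense eta-eta block from cached dressed integrals."""
    g = core.gamma
    lam2 = core.lam ** 2
    n = core.n
    dd = np.diag(D)
    v = dressed.v

    # one-electron part
    R1D = dressed.R1 * D
    H = -4.0 * g * (np.diag(R1D.sum(axis=1)) - R1D)

    # two-electron part; P4 contracted with the two-particle density
    P = dressed.P4
    r_t = (np.einsum("tqrs,tq,rs->t", P, D, D, optimize=True)
           - 0.5 * np.einsum("tqrs,ts,rq->t", P, D, D, optimize=True))
    A1 = (D * np.einsum("turs,rs->tu", P, D, optimize=True)
          - 0.5 * np.einsum("turs,ts,ru->tu", P, D, D, optimize=True))
    A2 = (np.einsum("tqus,tq,us->tu", P, D, D, optimize=True)
          - 0.5 * np.einsum("tqus,ts,uq->tu", P, D, D, optimize=True))
    A3 = (np.einsum("tqru,tq,ru->tu", P, D, D, optimize=True)
          - 0.5 * D * np.einsum("tqru,rq->tu", P, D, optimize=True))
    H += -4.0 * g * (np.diag(r_t) - A1 + A2 - A3)

    # cavity part
    H += lam2 * (np.outer(dd, dd) - 0.5 * D * D + np.diag(dd))
    H = 0.5 * (H + H.T)
    return DenseEtaEtaHessian(matrix=H)


def kk_diagonal_preconditioner(core: QEDCore, dressed: DressedIntegrals,
                               U: np.ndarray,
                               Fmo: np.ndarray | None = None,
                               floor: float = 1e-3) -> np.ndarray:
    """Fock-difference-dominated diagonal of the kappa-kappa block.

    The orbital Hessian diagonal is dominated by 4(F_aa - F_ii); entries are
    floored at a small positive constant for use as a preconditioner.
    """
    no = core.n_occ
    if Fmo is None:
        F = fock_dipole_basis(core, dressed, core.density(U))
        Fmo = U.T @ F @ U
    f = np.diag(Fmo)
    diag = 4.0 * (f[no:, None] - f[None, :no])
    return np.maximum(diag, floor)


def eta_diagonal_preconditioner(core: QEDCore, dressed: DressedIntegrals,
                                D: np.ndarray,
                                floor: float = 1e-3) -> np.ndarray:
    """Diagonal of the eta-eta block, floored, for the joint preconditioner."""
    g = core.gamma
    lam2 = core.lam ** 2
    n = core.n
    dd = np.diag(D)
    diag = -4.0 * g * ((dressed.R1 * D).sum(axis=1) - np.diag(dressed.R1 * D))
    P = dressed.P4
    r_t = (np.einsum("tqrs,tq,rs->t", P, D, D, optimize=True)
           - 0.5 * np.einsum("tqrs,ts,rq->t", P, D, D, optimize=True))
    Ptt = np.einsum("ttrs->trs", P)
    A1 = (dd * np.einsum("trs,rs->t", Ptt, D, optimize=True)
          - 0.5 * np.einsum("trs,ts,rt->t", Ptt, D, D, optimize=True))
    Ptut = np.einsum("tqts->tqs", P)
    A2 = (np.einsum("tqs,tq,ts->t", Ptut, D, D, optimize=True)
          - 0.5 * np.einsum("tqs,ts,tq->t", Ptut, D, D, optimize=True))
    Ptqrt = np.einsum("tqrt->tqr", P)
    A3 = (np.einsum("tqr,tq,rt->t", Ptqrt, D, D, optimize=True)
          - 0.5 * dd * np.einsum("tqr,rq->t", Ptqrt, D, optimize=True))
    diag += -4.0 * g * (r_t - A1 + A2 - A3)
    diag += lam2 * (dd * dd - 0.5 * dd * dd + dd)
    # the whole block scales with lambda^2, so the floor must be relative
    scale = np.abs(diag).max()
    eff_floor = max(1e-12, 1e-3 * scale) if scale > 0 else floor
    return np.maximum(diag, min(floor, eff_floor))


@dataclass
class HessianAction:
    """Matrix-free application of the (block-restricted) Hessian.

    The trial/result layout is the concatenation of the flattened (nv, no)
    kappa block and the length-n eta block.
    """

    core: QEDCore
    dressed: DressedIntegrals
    U: np.ndarray
    blocks_enabled: tuple[str, ...] = (KAPPA_KAPPA, ETA_ETA)

    def __post_init__(self):
        self.n = self.core.n
        self.no = self.core.n_occ
        self.nv = self.n - self.no
        self.nk = self.nv * self.no
        self.D = self.core.density(self.U)
        F = fock_dipole_basis(self.core, self.dressed, self.D)
        self.Fmo = self.U.T @ F @ self.U
        self.dim = self.nk + self.n
        # the eta-eta block is only N x N: assemble it once and apply by
        # matmul (lt_eta_eta remains the independent matrix-free reference)
        self._Hee = (build_dense_eta_eta(self.core, self.dressed,
                                         self.D).matrix
                     if ETA_ETA in self.blocks_enabled else None)

    def split(self, z: np.ndarray):
        return z[:self.nk].reshape(self.nv, self.no), z[self.nk:]

    def join(self, dkappa: np.ndarray, deta: np.ndarray) -> np.ndarray:
        return np.concatenate([dkappa.ravel(), deta])

    def apply(self, z: np.ndarray) -> np.ndarray:
        dk, de = self.split(np.asarray(z, float))
        out_k = np.zeros_like(dk)
        out_e = np.zeros_like(de)
        if KAPPA_KAPPA in self.blocks_enabled:
            out_k += lt_kappa_kappa(self.core, self.dressed, self.U, dk,
                                    Fmo=self.Fmo)
        if ETA_ETA in self.blocks_enabled:
            out_e += self._Hee @ de
        if MIXED in self.blocks_enabled:
            mk, me = lt_mixed(self.core, self.dressed, self.U, dk, de)
            out_k += mk
            out_e += me
        return self.join(out_k, out_e)

    def preconditioner(self, floor: float = 1e-3) -> np.ndarray:
        """Positive diagonal preconditioner over the joint vector."""
        pk = kk_diagonal_preconditioner(self.core, self.dressed, self.U,
                                        Fmo=self.Fmo, floor=floor)
        if self._Hee is not None:
            de = np.diag(self._Hee)
            scale = np.abs(de).max()
            pe = np.maximum(de, max(1e-12, 1e-3 * scale) if scale > 0
                            else floor)
        else:
            pe = np.full(self.n, 1.0)
        return np.concatenate([pk.ravel(), pe])

    def block_preconditioner(self, floor: float = 1e-3):
        """Shift-aware block preconditioner ``(residual, mu) -> direction``.

        The kappa block uses the Fock-difference diagonal; the eta block
        applies the exact (level-shifted) inverse of the dense eta-eta
        Hessian, which is only N x N.  With the mixed blocks disabled this
        makes the eta part of the Newton equations exact in a single
        micro-iteration.
        """
        pk = kk_diagonal_preconditioner(self.core, self.dressed, self.U,
                                        Fmo=self.Fmo, floor=floor).ravel()
        if self._Hee is not None:
            w, Q = np.linalg.eigh(self._Hee)
            scale = max(np.abs(w).max(), 1e-12)
            wfloor = 1e-6 * scale
        else:
            w = Q = None

        def apply(r, mu):
            out = np.empty_like(r)
            out[:self.nk] = r[:self.nk] / (pk + mu)
            if Q is None:
                out[self.nk:] = r[self.nk:]
            else:
                denom = np.maximum(w + mu, wfloor)
                out[self.nk:] = Q @ ((Q.T @ r[self.nk:]) / denom)
            return out

        return apply
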