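"""Restricted Hartree-Fock in the AO basis.

A standard textbook Roothaan-Hall/DIIS implementation working directly on
the raw AO integrals.  It provides the cavity-free initial orbitals for the
polaritonic solvers and serves as the independent zero-coupling reference:
its energy assembly never touches the dipole-basis or dressed-integral code
paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .integrals import AOIntegralSet


@dataclass
class RHFResult:
    energy: float
    mo_coeff: np.ndarray     # (n, n) AO x MO
    mo_energy: np.ndarray
    n_occ: int
    converged: bool
    n_iterations: int


def _fock(h, eri, D):
    J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
    K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
    return h + J - 0.5 * K


def rhf_energy(h, eri, D, e_nuc):
    """RHF energy for a given AO density (closed-shell convention tr(DS)=N)."""
    F = _fock(h, eri, D)
    return 0.5 * np.einsum("pq,pq->", D, h + F) + e_nuc


def run_rhf(ints: AOIntegralSet, n_electrons: int,
            conv_tol: float = 1e-12, max_iter: int = 200,
            diis_dim: int = 8) -> RHFResult:
    """Solve RHF with DIIS acceleration from a core-Hamiltonian guess."""
    if n_electrons % 2:
        raise ValueError("closed-shell RHF needs an even electron count")
    n_occ = n_electrons // 2
    S, h, eri = ints.overlap, ints.core_h, ints.eri
    # symmetric orthogonalization
    w, U = np.linalg.eigh(S)
    if w.min() <= 1e-10:
        raise ValueError("AO overlap is numerically singular")
    X = U @ np.diag(w ** -0.5) @ U.T

    def density(C):
        Co = C[:, :n_occ]
        return 2.0 * Co @ Co.T

    e, C = scipy.linalg.eigh(h, S)
    D = density(C)
    energy = rhf_energy(h, eri, D, ints.e_nuc)
    errs, focks = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = _fock(h, eri, D)
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        errs.append(err.ravel())
        focks.append(F)
        if len(errs) > diis_dim:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = errs[i] @ errs[j]
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, focks))
            except np.linalg.LinAlgError:
                pass
        e, C = scipy.linalg.eigh(F, S)
        D = density(C)
        new_energy = rhf_energy(h, eri, D, ints.e_nuc)
        grad = np.max(np.abs(errs[-1]))
        if abs(new_energy - energy) < conv_tol and grad < 1e-8:
            energy = new_energy
            converged = True
            break
        energy = new_energy
    return RHFResult(energy=energy, mo_coeff=C, mo_energy=e, n_occ=n_occ,
                     converged=converged, n_iterations=it)
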