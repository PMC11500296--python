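"""Independent oracles: finite differences, exact polariton diagonalization,
origin invariance, and the zero-coupling reduction.

Everything here is deliberately implemented apart from the production code
paths it checks: the exact-diagonalization oracle builds the length-gauge
Hamiltonian in an explicit (determinant) x (photon number) basis with its
own second-quantization algebra, and the finite-difference oracle only ever
calls the public energy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .integrals import fetch_ao_integrals
from .optimizers import run_gb_dbi, run_gb_diis, run_tr_nr
from .qed import QEDCore, dress_integrals, scqed_energy
from .rhf import run_rhf
from .system import CavityConfig, MolecularSystem, RunConfig


# ----------------------------------------------------------------------
# finite differences
# ----------------------------------------------------------------------

def fd_gradient(func, x: np.ndarray, direction: np.ndarray,
                step: float = 1e-4) -> float:
    """Central-difference directional derivative (f(x+h d) - f(x-h d))/2h."""
    if step <= 0:
        raise ValueError("step must be positive")
    x = np.asarray(x, float)
    d = np.asarray(direction, float)
    fp = func(x + step * d)
    fm = func(x - step * d)
    if not (np.isfinite(fp) and np.isfinite(fm)):
        raise ArithmeticError("non-finite energy at displaced point")
    return (fp - fm) / (2.0 * step)


# ----------------------------------------------------------------------
# exact polariton ground state (tiny systems)
# ----------------------------------------------------------------------

def _apply_annihilation(states: dict, so: int) -> dict:
    out = {}
    for occ, c in states.items():
        if not (occ >> so) & 1:
            continue
        sign = (-1) ** bin(occ & ((1 << so) - 1)).count("1")
        out[occ & ~(1 << so)] = out.get(occ & ~(1 << so), 0.0) + sign * c
    return out


def _apply_creation(states: dict, so: int) -> dict:
    out = {}
    for occ, c in states.items():
        if (occ >> so) & 1:
            continue
        sign = (-1) ** bin(occ & ((1 << so) - 1)).count("1")
        out[occ | (1 << so)] = out.get(occ | (1 << so), 0.0) + sign * c
    return out


def _operator_matrix(dets: list[int], terms) -> np.ndarray:
    """Matrix of a sum of second-quantized strings over determinants.

    ``terms`` is an iterable of (coefficient, [ops]) where each op is
    ('c', so) for creation or ('a', so) for annihilation, applied right to
    left.
    """
    index = {d: i for i, d in enumerate(dets)}
    H = np.zeros((len(dets), len(dets)))
    for coef, ops in terms:
        if coef == 0.0:
            continue
        for j, det in enumerate(dets):
            states = {det: 1.0}
            for kind, so in reversed(ops):
                states = (_apply_creation(states, so) if kind == "c"
                          else _apply_annihilation(states, so))
                if not states:
                    break
            for occ, c in states.items():
                i = index.get(occ)
                if i is not None:
                    H[i, j] += coef * c
    return H


def _electronic_matrices(h: np.ndarray, g: np.ndarray, dip: np.ndarray,
                         n_electrons: int):
    """Determinant-basis matrices of H_el (without E_nuc) and (d.eps)_el."""
    K = h.shape[0]
    n_so = 2 * K
    dets = [sum(1 << s for s in occ)
            for occ in itertools.combinations(range(n_so), n_electrons)]

    def spin_pairs(p, q):
        # E_pq = sum_sigma a+_{p sigma} a_{q sigma}; even bits alpha, odd beta
        return [((2 * p, 2 * q)), ((2 * p + 1, 2 * q + 1))]

    one_terms = []
    dip_terms = []
    for p in range(K):
        for q in range(K):
            for (cp, aq) in spin_pairs(p, q):
                one_terms.append((h[p, q], [("c", cp), ("a", aq)]))
                dip_terms.append((dip[p, q], [("c", cp), ("a", aq)]))
    two_terms = []
    for p in range(K):
        for q in range(K):
            for r in range(K):
                for s in range(K):
                    coef = 0.5 * g[p, q, r, s]
                    if coef == 0.0:
                        continue
                    for (cp, aq) in spin_pairs(p, q):
                        for (cr, as_) in spin_pairs(r, s):
                            # e_pqrs = a+_p a+_r a_s a_q (spin-summed)
                            two_terms.append(
                                (coef, [("c", cp), ("c", cr),
                                        ("a", as_), ("a", aq)]))
    Hel = _operator_matrix(dets, one_terms) + _operator_matrix(dets, two_terms)
    Del = _operator_matrix(dets, dip_terms)
    return dets, Hel, Del


@dataclass
class FockSpaceModel:
    """Explicit Pauli-Fierz Hamiltonian in (determinants) x (photon number)."""

    n_max: int
    hamiltonian: np.ndarray
    n_determinants: int

    def ground_state_energy(self) -> float:
        return float(np.linalg.eigvalsh(self.hamiltonian)[0])


def build_fock_space_model(system: MolecularSystem, cavity: CavityConfig,
                           n_max: int = 10,
                           max_determinants: int = 80) -> FockSpaceModel:
    """Exact length-gauge Hamiltonian for a tiny electronic space.

    Includes the bilinear coupling and the full dipole self-energy; refuses
    systems whose determinant space exceeds ``max_determinants`` (the oracle
    exists to validate the Hamiltonian terms, not to scale).
    """
    if n_max < 1:
        raise ValueError("photon cutoff must be at least 1")
    ints = fetch_ao_integrals(system)
    rhf = run_rhf(ints, system.n_electrons)
    C = rhf.mo_coeff
    K = C.shape[1]
    n_det = math.comb(2 * K, system.n_electrons)
    if n_det > max_determinants:
        raise ValueError(
            f"{n_det} determinants: the exact-diagonalization oracle is "
            f"restricted to tiny systems (<= {max_determinants})")
    h = C.T @ ints.core_h @ C
    g = np.einsum("pi,qj,pqrs,rk,sl->ijkl", C, C, ints.eri, C, C,
                  optimize=True)
    eps = cavity.polarization
    dip = C.T @ (-np.einsum("k,kpq->pq", eps, ints.dipole_e)) @ C
    d_n = float(eps @ ints.d_nuc)

    dets, Hel, Del = _electronic_matrices(h, g, dip, system.n_electrons)
    nd = len(dets)
    Hel += (ints.e_nuc) * np.eye(nd)
    Dtot = Del + d_n * np.eye(nd)

    lam, omega = cavity.lambda_coupling, cavity.omega
    nph = n_max + 1
    nhat = np.diag(np.arange(nph, dtype=float))
    bpbd = np.zeros((nph, nph))
    for n in range(n_max):
        bpbd[n, n + 1] = bpbd[n + 1, n] = math.sqrt(n + 1.0)

    H = (np.kron(Hel, np.eye(nph))
         + omega * np.kron(np.eye(nd), nhat)
         - lam * math.sqrt(omega / 2.0) * np.kron(Dtot, bpbd)
         + 0.5 * lam ** 2 * np.kron(Dtot @ Dtot, np.eye(nph)))
    return FockSpaceModel(n_max=n_max, hamiltonian=H, n_determinants=nd)


def exact_polariton_ground_state(system: MolecularSystem,
                                 cavity: CavityConfig,
                                 n_max: int = 10) -> float:
    """n_max-converged exact ground-state energy of the one-mode Hamiltonian."""
    model = build_fock_space_model(system, cavity, n_max=n_max)
    return model.ground_state_energy()


# ----------------------------------------------------------------------
# invariance / limit checks
# ----------------------------------------------------------------------

def origin_invariance_check(system: MolecularSystem, cavity: CavityConfig,
                            translation, cfg: RunConfig | None = None,
                            frozen_eta: bool = False) -> float:
    """|E(translated) - E(original)| for converged SC-QED-HF.

    With ``frozen_eta`` the coherent-state parameters are pinned at zero,
    which removes the mechanism that reabsorbs the dipole shift of a charged
    molecule and exposes the origin dependence of the uncorrelated
    treatment.  Only the component of the translation along the cavity
    polarization couples; use a translation with a component along eps when
    probing the ablation.
    """
    cfg = cfg or RunConfig(algorithm="tr_nr", max_iterations=100)
    shifted = system.translated(translation)

    def solve(s):
        if frozen_eta:
            zcfg = RunConfig(algorithm="gb_diis",
                             energy_threshold=cfg.energy_threshold,
                             gradient_threshold=max(cfg.gradient_threshold,
                                                    1e-8),
                             max_iterations=max(cfg.max_iterations, 200))
            st, rep = run_gb_diis(s, cavity, zcfg,
                                  frozen_eta=np.zeros(1))
            # frozen_eta length is fixed up inside the driver via core.n
            return st, rep
        return run_tr_nr(s, cavity, cfg)

    st1, rep1 = solve(system)
    st2, rep2 = solve(shifted)
    if not (rep1.converged and rep2.converged):
        raise RuntimeError("origin-invariance check inconclusive: "
                           "one of the runs did not converge")
    return abs(st1.energy - st2.energy)


def rhf_limit_check(system: MolecularSystem, cavity_omega: float = 0.1,
                    algorithm: str = "tr_nr") -> float:
    """|E_SCQEDHF(lambda=0) - E_RHF| with the plain AO-basis RHF as oracle."""
    ints = fetch_ao_integrals(system)
    rhf = run_rhf(ints, system.n_electrons)
    cav = CavityConfig(omega=cavity_omega, lambda_coupling=0.0,
                       polarization=np.array([0.0, 0.0, 1.0]))
    cfg = RunConfig(algorithm=algorithm, max_iterations=200)
    driver = {"tr_nr": run_tr_nr, "gb_dbi": run_gb_dbi,
              "gb_diis": run_gb_diis}[cfg.algorithm]
    st, rep = driver(system, cav, cfg, ints=ints)
    return abs(st.energy - rhf.energy)


# ----------------------------------------------------------------------
# self test
# ----------------------------------------------------------------------

def selftest(verbose: bool = True) -> list[tuple[str, float, float, bool]]:
    """Run the oracle suite on the embedded fixtures; returns rows of
    (check, value, tolerance, passed)."""
    from .fixtures import ammonium, h2, water

    rows = []

    def add(name, value, tol):
        rows.append((name, float(value), tol, bool(value < tol)))

    for alg in ("gb_diis", "tr_nr", "gb_dbi"):
        add(f"rhf-limit[{alg}] H2O/STO-3G", rhf_limit_check(water(), algorithm=alg), 1e-9)

    sys_h2 = h2()
    cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                       polarization=np.array([0.0, 0.0, 1.0]))
    e_exact = exact_polariton_ground_state(sys_h2, cav, n_max=10)
    st, rep = run_tr_nr(sys_h2, cav)
    add("variational bound H2 (E_scf - E_exact >= -1e-10)",
        max(0.0, e_exact - st.energy), 1e-10)

    nh4 = ammonium()
    cav2 = CavityConfig(omega=0.1, lambda_coupling=0.01,
                        polarization=np.array([0.0, 0.0, 1.0]))
    add("origin invariance NH4+ (10 bohr along eps)",
        origin_invariance_check(nh4, cav2, (0.0, 0.0, 10.0)), 1e-8)

    if verbose:
        for name, value, tol, ok in rows:
            print(f"{'PASS' if ok else 'FAIL'}  {name:45s} {value:10.3e} "
                  f"(tol {tol:.0e})")
    return rows
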