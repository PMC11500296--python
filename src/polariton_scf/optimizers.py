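"""SCF drivers for SC-QED-HF.

Three optimizers over the joint (kappa, eta) parametrization:

``gb_diis``
    The gradient-based baseline: Roothaan-Hall diagonalization of the
    dressed Fock matrix with DIIS for the density, damped steepest descent
    with DIIS for eta.  Documented to stagnate on the eta parameters for
    harder cases (the eta-eta curvature is strongly non-diagonal, so a
    gradient step is a poor preconditioner).

``tr_nr``
    Trust-region Newton-Raphson on the concatenated (kappa, eta) vector
    using the kappa-kappa and eta-eta Hessian blocks (mixed blocks
    optional).  The level-shifted Newton equations are solved matrix-free
    in a Davidson-type subspace with a diagonal preconditioner;
    micro-iterations are counted as Hessian-vector products.

``gb_dbi``
    Roothaan-Hall/DIIS for the orbitals as in the baseline, but a Newton
    step for eta from direct inversion of the dense eta-eta Hessian block
    (eigenvalue-floored pseudo-inverse; damped gradient fallback while the
    block is not positive definite).  No micro-iterations.

All drivers are deterministic and share the convergence metrics: the
absolute energy change, the largest element of the joint gradient, and the
L2 norms of the kappa and eta gradients scaled by the number of
nonredundant parameters in each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .hessian import ETA_ETA, KAPPA_KAPPA, MIXED, HessianAction, build_dense_eta_eta
from .integrals import AOIntegralSet, fetch_ao_integrals
from .qed import (QEDCore, SCQEDState, apply_kappa, dress_integrals,
                  eta_gradient, fock_dipole_basis, kappa_gradient,
                  scqed_energy)
from .rhf import run_rhf
from .system import CavityConfig, MolecularSystem, RunConfig


# ----------------------------------------------------------------------
# DIIS
# ----------------------------------------------------------------------

class DIISBuffer:
    """Ring buffer of (parameter, error) pairs for DIIS extrapolation."""

    def __init__(self, max_dim: int = 8):
        if max_dim < 1:
            raise ValueError("DIIS dimension must be >= 1")
        self.max_dim = max_dim
        self.params: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def push(self, param: np.ndarray, error: np.ndarray) -> None:
        self.params.append(np.asarray(param, float).copy())
        self.errors.append(np.asarray(error, float).ravel().copy())
        if len(self.params) > self.max_dim:
            self.params.pop(0)
            self.errors.pop(0)

    def __len__(self) -> int:
        return len(self.params)


def diis_extrapolate(buffer: DIISBuffer) -> np.ndarray:
    """Standard DIIS least-squares extrapolation with Lagrange normalization.

    Falls back to the newest parameter vector if the B matrix is singular
    beyond tolerance.  Coefficients sum to one.
    """
    m = len(buffer)
    if m == 0:
        raise ValueError("DIIS buffer is empty")
    if m == 1:
        return buffer.params[-1].copy()
    B = np.empty((m + 1, m + 1))
    B[:m, :m] = np.array([[ei @ ej for ej in buffer.errors]
                          for ei in buffer.errors])
    B[m, :m] = B[:m, m] = -1.0
    B[m, m] = 0.0
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        scale = np.abs(np.diag(B[:m, :m])).max()
        if scale <= 0 or not np.isfinite(scale):
            return buffer.params[-1].copy()
        c = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        return buffer.params[-1].copy()
    if not np.all(np.isfinite(c)) or np.abs(c).sum() > 1e8:
        return buffer.params[-1].copy()
    out = np.zeros_like(buffer.params[0])
    for ci, pi in zip(c, buffer.params):
        out += ci * pi
    return out


# ----------------------------------------------------------------------
# convergence bookkeeping
# ----------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    energy: float
    delta_e: float          # nan on the first iteration
    max_grad: float         # max |E^(1)| over kappa and eta
    kappa_norm_scaled: float
    eta_norm_scaled: float
    micro_iterations: int = 0
    radius: float = math.nan
    mu: float = math.nan

    def log_line(self) -> str:
        de = "      n/a   " if math.isnan(self.delta_e) else f"{self.delta_e:12.4e}"
        extra = ""
        if not math.isnan(self.radius):
            extra = f"  r={self.radius:8.4f}  mu={self.mu:10.4e}"
        return (f"iter {self.iteration:4d}  E={self.energy:20.12f}  "
                f"dE={de}  max|E1|={self.max_grad:12.4e}  "
                f"|gk|/Nk={self.kappa_norm_scaled:12.4e}  "
                f"|ge|/Ne={self.eta_norm_scaled:12.4e}  "
                f"micro={self.micro_iterations:3d}{extra}")


def convergence_metrics(energy: float, prev_energy: float | None,
                        g_kappa: np.ndarray, g_eta: np.ndarray):
    """Per-iteration diagnostics: |dE|, max |E^(1)|, scaled gradient norms.

    The scaled norms divide the L2 norm by the number of nonredundant
    parameters in each class (n_occ * n_virt for kappa, n_orbitals for eta).
    """
    delta_e = math.nan if prev_energy is None else abs(energy - prev_energy)
    gk = np.asarray(g_kappa).ravel()
    ge = np.asarray(g_eta).ravel()
    allg = np.concatenate([gk, ge])
    max_grad = float(np.abs(allg).max()) if allg.size else 0.0
    nk = max(gk.size, 1)
    ne = max(ge.size, 1)
    return (delta_e, max_grad,
            float(np.linalg.norm(gk)) / nk, float(np.linalg.norm(ge)) / ne)


@dataclass
class ConvergenceReport:
    algorithm: str
    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    n_macro: int = 0            # iterations in which a step was taken

    def append(self, rec: IterationRecord):
        self.records.append(rec)

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    @property
    def total_micro_iterations(self) -> int:
        return sum(r.micro_iterations for r in self.records)

    @property
    def mean_micro_iterations(self) -> float:
        n = max(self.n_macro, 1)
        return self.total_micro_iterations / n

    def log(self) -> str:
        head = (f"# algorithm={self.algorithm} converged={self.converged} "
                f"macro={self.n_macro}")
        return "\n".join([head] + [r.log_line() for r in self.records])


# ----------------------------------------------------------------------
# trust-region step (reduced-space level-shifted Newton)
# ----------------------------------------------------------------------

@dataclass
class TrustRegionState:
    radius: float = 0.5
    mu: float = 0.0
    gain_ratio: float = math.nan
    r_min: float = 1e-5
    r_max: float = 32.0

    def update(self, gain: float, at_boundary: bool = True) -> bool:
        """Adjust the radius; returns True if the step is accepted.

        Standard policy: double the radius after a well-predicted step that
        was limited by the boundary, shrink on a poorly predicted one,
        reject (and shrink harder) on an energy increase.
        """
        self.gain_ratio = gain
        if gain < 0.0:
            self.radius = max(self.r_min, 0.5 * self.radius)
            return False
        if gain < 0.25:
            self.radius = max(self.r_min, 0.7 * self.radius)
        elif gain > 0.75 and at_boundary:
            self.radius = min(self.r_max, 2.0 * self.radius)
        return True


def _subspace_step(Hs: np.ndarray, gs: np.ndarray, radius: float):
    """Solve the level-shifted trust-region subproblem in the subspace."""
    w, Q = np.linalg.eigh(0.5 * (Hs + Hs.T))
    gq = Q.T @ gs

    def step_norm(mu):
        return np.linalg.norm(gq / (w + mu))

    if w.min() > 1e-12 and step_norm(0.0) <= radius:
        a = -Q @ (gq / w)
        return a, 0.0
    # boundary solution: find mu > -w_min with ||a(mu)|| = radius
    mu_lo = max(0.0, -w.min()) + 1e-14
    mu = mu_lo + 1e-10
    while step_norm(mu) > radius and mu < 1e12:
        mu = 2.0 * mu + 1e-8
    lo, hi = mu_lo, mu
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if step_norm(mid) > radius:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14 * max(1.0, hi):
            break
    mu = 0.5 * (lo + hi)
    a = -Q @ (gq / (w + mu))
    return a, mu


def solve_trust_region_step(action: HessianAction, gradient: np.ndarray,
                            trust: TrustRegionState,
                            precond=None,
                            tol: float = 1e-6, max_micro: int = 100):
    """Level-shifted Newton step, matrix-free in a Davidson-type subspace.

    Returns ``(step, mu, micro_iterations, Hstep)``; micro-iterations count
    Hessian-vector products.  The residual of the level-shifted system
    ``(H + mu I) dz = -g`` (mu >= 0, the Levenberg-Marquardt damping; zero
    whenever the unconstrained Newton step fits in the radius) is driven
    below ``tol``.  ``precond`` may be a positive diagonal vector or
    a callable ``(residual, mu) -> direction`` applying an approximate
    shifted inverse (the drivers pass the exact eta-eta block inverse plus
    the Fock-difference kappa diagonal).
    """
    g = np.asarray(gradient, float).ravel()
    gnorm = np.linalg.norm(g)
    if precond is None:
        diag = np.ones_like(g)
        precond = lambda r, mu: r / (diag + mu)
    elif isinstance(precond, np.ndarray):
        diag = np.maximum(np.abs(precond), 1e-8)
        precond = lambda r, mu: r / (diag + mu)
    if gnorm == 0.0:
        return np.zeros_like(g), 0.0, 0, np.zeros_like(g)

    B: list[np.ndarray] = []
    Sg: list[np.ndarray] = []
    t = precond(-g, 0.0)
    micro = 0
    step = np.zeros_like(g)
    mu = 0.0
    Hstep = np.zeros_like(g)
    for micro in range(1, max_micro + 1):
        # orthonormalize the new direction against the subspace
        for b in B:
            t -= (b @ t) * b
        tn = np.linalg.norm(t)
        if tn < 1e-12 * max(1.0, gnorm):
            micro -= 1
            break
        b = t / tn
        B.append(b)
        Sg.append(action.apply(b))
        Bm = np.column_stack(B)
        Sm = np.column_stack(Sg)
        Hs = Bm.T @ Sm
        gs = Bm.T @ g
        a, mu = _subspace_step(Hs, gs, trust.radius)
        step = Bm @ a
        Hstep = Sm @ a
        resid = Hstep + mu * step + g
        if np.linalg.norm(resid) <= tol:
            break
        t = precond(-resid, mu)
    return step, mu, micro, Hstep


# ----------------------------------------------------------------------
# shared driver scaffolding
# ----------------------------------------------------------------------

def _initial_state(system: MolecularSystem, cavity: CavityConfig,
                   ints: AOIntegralSet | None = None):
    """Cavity-free RHF orbitals + eta at the dipole eigenvalues."""
    if ints is None:
        ints = fetch_ao_integrals(system)
    rhf = run_rhf(ints, system.n_electrons)
    core = QEDCore(ints, cavity, system.n_electrons)
    U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
    # re-orthonormalize against accumulated roundoff
    uu, _, vv = np.linalg.svd(U0)
    U0 = uu @ vv
    eta0 = core.d_diag.copy()
    return core, U0, eta0


def _aufbau_from_fock(F: np.ndarray) -> np.ndarray:
    """Orbitals (columns, ascending eigenvalue) of a dipole-basis Fock."""
    _, U = np.linalg.eigh(F)
    return U


def _finish(core, U, eta, report, state_energy) -> SCQEDState:
    state = SCQEDState(core=core, U=U, eta=eta, energy=state_energy)
    return state


# ----------------------------------------------------------------------
# gb-DIIS baseline
# ----------------------------------------------------------------------

def run_gb_diis(system: MolecularSystem, cavity: CavityConfig,
                cfg: RunConfig | None = None,
                ints: AOIntegralSet | None = None,
                initial=None,
                frozen_eta: np.ndarray | None = None):
    """Gradient-based baseline: Roothaan-Hall/DIIS + steepest-descent eta.

    ``frozen_eta`` pins the coherent-state parameters (used by the
    origin-invariance ablation); pass zeros to recover the uncorrelated
    QED-HF-style treatment.
    """
    cfg = cfg or RunConfig(algorithm="gb_diis")
    core, U, eta = _initial_state(system, cavity, ints)
    if initial is not None:
        U, eta = np.asarray(initial[0], float), np.asarray(initial[1], float)
    if frozen_eta is not None:
        eta = np.broadcast_to(np.asarray(frozen_eta, float),
                              (core.n,)).copy()
    report = ConvergenceReport(algorithm="gb_diis")
    fock_diis = DIISBuffer(cfg.diis_dim)
    eta_diis = DIISBuffer(cfg.diis_dim)
    prev_e = None
    energy = math.nan
    for it in range(1, cfg.max_iterations + 1):
        dressed = dress_integrals(core, eta)
        D = core.density(U)
        F = fock_dipole_basis(core, dressed, D)
        energy = scqed_energy(core, dressed, D)
        gk = 4.0 * (U.T @ F @ U)[core.n_occ:, :core.n_occ]
        ge = (np.zeros(core.n) if frozen_eta is not None
              else eta_gradient(core, dressed, D))
        de, gmax, gkn, gen = convergence_metrics(energy, prev_e, gk, ge)
        report.append(IterationRecord(it, energy, de, gmax, gkn, gen))
        if (prev_e is not None and de < cfg.energy_threshold
                and gmax < cfg.gradient_threshold):
            report.converged = True
            break
        prev_e = energy
        report.n_macro += 1
        # density update: DIIS over dressed Fock matrices
        err = F @ D - D @ F
        fock_diis.push(F, err)
        Fx = diis_extrapolate(fock_diis).reshape(core.n, core.n)
        U = _aufbau_from_fock(0.5 * (Fx + Fx.T))
        # eta update: damped steepest descent accelerated by DIIS
        if frozen_eta is None:
            eta_new = eta - cfg.eta_step * ge
            eta_diis.push(eta_new, ge)
            eta = diis_extrapolate(eta_diis)
    state = _finish(core, U, eta, report, energy)
    return state, report


# ----------------------------------------------------------------------
# trust-region Newton-Raphson
# ----------------------------------------------------------------------

def run_tr_nr(system: MolecularSystem, cavity: CavityConfig,
              cfg: RunConfig | None = None,
              ints: AOIntegralSet | None = None,
              initial=None):
    """Second-order optimizer on the joint (kappa, eta) vector."""
    cfg = cfg or RunConfig(algorithm="tr_nr")
    core, U, eta = _initial_state(system, cavity, ints)
    if initial is not None:
        U, eta = np.asarray(initial[0], float), np.asarray(initial[1], float)
    blocks = (KAPPA_KAPPA, ETA_ETA, MIXED) if cfg.use_mixed_blocks \
        else (KAPPA_KAPPA, ETA_ETA)
    report = ConvergenceReport(algorithm="tr_nr")
    trust = TrustRegionState(radius=cfg.trust_radius_init)
    prev_e = None
    dressed = dress_integrals(core, eta)
    energy = scqed_energy(core, dressed, core.density(U))
    for it in range(1, cfg.max_iterations + 1):
        D = core.density(U)
        gk = kappa_gradient(core, dressed, U)
        ge = eta_gradient(core, dressed, D)
        de, gmax, gkn, gen = convergence_metrics(energy, prev_e, gk, ge)
        if (prev_e is not None and de < cfg.energy_threshold
                and gmax < cfg.gradient_threshold):
            report.append(IterationRecord(it, energy, de, gmax, gkn, gen,
                                          0, trust.radius, trust.mu))
            report.converged = True
            break
        prev_e = energy
        action = HessianAction(core, dressed, U, blocks_enabled=blocks)
        g = action.join(gk, ge)
        tol = max(min(1e-2 * np.linalg.norm(g), cfg.micro_tolerance), 1e-13)
        micro_total = 0
        accepted = False
        for _attempt in range(8):
            step, mu, micro, Hstep = solve_trust_region_step(
                action, g, trust, action.block_preconditioner(),
                tol=tol, max_micro=cfg.micro_max)
            micro_total += micro
            dk, de_step = action.split(step)
            U_new = apply_kappa(U, dk, core.n_occ)
            eta_new = eta + de_step
            dressed_new = dress_integrals(core, eta_new)
            e_new = scqed_energy(core, dressed_new, core.density(U_new))
            predicted = float(g @ step + 0.5 * step @ Hstep)
            decrease = e_new - energy
            # slack at the roundoff floor of the energy evaluation
            slack = max(1e-13, 1e-14 * abs(energy))
            if decrease <= slack:
                gain = (decrease / predicted if predicted < 0
                        else (1.0 if decrease < 0 else 0.5))
                at_boundary = np.linalg.norm(step) >= 0.9 * trust.radius
                trust.update(gain, at_boundary)
                U, eta, dressed, energy = U_new, eta_new, dressed_new, e_new
                trust.mu = mu
                accepted = True
                break
            trust.update(-1.0)  # reject: shrink the radius and retry
        report.n_macro += 1
        report.append(IterationRecord(it, energy, de, gmax, gkn, gen,
                                      micro_total, trust.radius, trust.mu))
        if not accepted:
            # cannot make progress within the radius bounds
            break
    state = _finish(core, U, eta, report, energy)
    return state, report


# ----------------------------------------------------------------------
# gb-DBI: DIIS orbitals + direct inversion of the eta-eta block
# ----------------------------------------------------------------------

def run_gb_dbi(system: MolecularSystem, cavity: CavityConfig,
               cfg: RunConfig | None = None,
               ints: AOIntegralSet | None = None,
               initial=None):
    """DIIS density update + Newton eta step from the dense eta-eta block."""
    cfg = cfg or RunConfig(algorithm="gb_dbi")
    core, U, eta = _initial_state(system, cavity, ints)
    if initial is not None:
        U, eta = np.asarray(initial[0], float), np.asarray(initial[1], float)
    report = ConvergenceReport(algorithm="gb_dbi")
    fock_diis = DIISBuffer(cfg.diis_dim)
    prev_e = None
    energy = math.nan
    for it in range(1, cfg.max_iterations + 1):
        dressed = dress_integrals(core, eta)
        D = core.density(U)
        F = fock_dipole_basis(core, dressed, D)
        energy = scqed_energy(core, dressed, D)
        gk = 4.0 * (U.T @ F @ U)[core.n_occ:, :core.n_occ]
        ge = eta_gradient(core, dressed, D)
        de, gmax, gkn, gen = convergence_metrics(energy, prev_e, gk, ge)
        report.append(IterationRecord(it, energy, de, gmax, gkn, gen))
        if (prev_e is not None and de < cfg.energy_threshold
                and gmax < cfg.gradient_threshold):
            report.converged = True
            break
        prev_e = energy
        report.n_macro += 1
        err = F @ D - D @ F
        fock_diis.push(F, err)
        Fx = diis_extrapolate(fock_diis).reshape(core.n, core.n)
        U = _aufbau_from_fock(0.5 * (Fx + Fx.T))
        # eta Newton step by direct inversion of the dense eta-eta block
        Hee = build_dense_eta_eta(core, dressed, D).matrix
        w, Q = np.linalg.eigh(Hee)
        if w.min() < -1e-10:
            # not yet positive definite: damped gradient step this iteration
            eta = eta - cfg.eta_step * ge
        else:
            winv = 1.0 / np.maximum(w, 1e-8)
            eta = eta - Q @ (winv * (Q.T @ ge))
    state = _finish(core, U, eta, report, energy)
    return state, report


_DRIVERS = {"gb_diis": run_gb_diis, "tr_nr": run_tr_nr, "gb_dbi": run_gb_dbi}


def run_scf(system: MolecularSystem, cavity: CavityConfig,
            cfg: RunConfig | None = None,
            ints: AOIntegralSet | None = None,
            initial=None):
    """Dispatch to the driver named in the run configuration."""
    cfg = cfg or RunConfig()
    return _DRIVERS[cfg.algorithm](system, cavity, cfg, ints=ints,
                                   initial=initial)
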