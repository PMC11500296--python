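"""Hessian linear transformations, dense eta-eta block, preconditioners."""

import numpy as np
import pytest

from polariton_scf.hessian import (HessianAction, build_dense_eta_eta,
                                   eta_diagonal_preconditioner,
                                   kk_diagonal_preconditioner,
                                   lt_eta_eta, lt_kappa_kappa, lt_mixed)
from polariton_scf.qed import (QEDCore, apply_kappa, dress_integrals,
                               eta_gradient, kappa_gradient, scqed_energy)
from polariton_scf.system import CavityConfig


def test_lt_eta_eta_matches_gradient_fd(qed_point):
    core, U, eta, dressed, rng = qed_point
    D = core.density(U)
    x = rng.standard_normal(core.n)
    Hx = lt_eta_eta(core, dressed, D, x)
    h = 1e-4
    gp = eta_gradient(core, dress_integrals(core, eta + h * x), D)
    gm = eta_gradient(core, dress_integrals(core, eta - h * x), D)
    assert np.abs(Hx - (gp - gm) / (2 * h)).max() < 1e-6


def test_lt_eta_eta_zero_at_zero_coupling(water_sto):
    system, ints, rhf = water_sto
    cav0 = CavityConfig(omega=0.5, lambda_coupling=0.0,
                        polarization=np.array([0.0, 0.0, 1.0]))
    core = QEDCore(ints, cav0, 10)
    U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
    d = dress_integrals(core, core.d_diag)
    out = lt_eta_eta(core, d, core.density(U0), np.ones(core.n))
    assert np.abs(out).max() == 0.0


def test_lt_kappa_kappa_zero_trial(qed_point):
    core, U, eta, dressed, rng = qed_point
    no, nv = core.n_occ, core.n - core.n_occ
    out = lt_kappa_kappa(core, dressed, U, np.zeros((nv, no)))
    assert np.abs(out).max() == 0.0


def test_lt_kappa_kappa_energy_bilinear_fd(qed_point):
    """u^T H x equals the mixed second difference of the energy."""
    core, U, eta, dressed, rng = qed_point
    no, nv = core.n_occ, core.n - core.n_occ
    x = rng.standard_normal((nv, no))
    u = rng.standard_normal((nv, no))
    val = float(np.sum(u * lt_kappa_kappa(core, dressed, U, x)))

    def E(dk):
        return scqed_energy(core, dressed,
                            core.density(apply_kappa(U, dk, no)))

    h = 1e-4
    fd = (E(h * (x + u)) + E(-h * (x + u))
          - E(h * (x - u)) - E(-h * (x - u))) / (4 * h * h)
    assert val == pytest.approx(fd, abs=1e-5 * max(1.0, abs(val)))


def test_lt_kappa_kappa_symmetry(qed_point):
    core, U, eta, dressed, rng = qed_point
    no, nv = core.n_occ, core.n - core.n_occ
    x = rng.standard_normal((nv, no))
    y = rng.standard_normal((nv, no))
    Hx = lt_kappa_kappa(core, dressed, U, x)
    Hy = lt_kappa_kappa(core, dressed, U, y)
    assert float(np.sum(y * Hx)) == pytest.approx(float(np.sum(x * Hy)),
                                                  abs=1e-8)


def test_dense_eta_eta_equals_lt_on_unit_vectors(qed_point):
    core, U, eta, dressed, rng = qed_point
    D = core.density(U)
    dense = build_dense_eta_eta(core, dressed, D).matrix
    assert np.abs(dense - dense.T).max() < 1e-10
    cols = np.column_stack(
        [lt_eta_eta(core, dressed, D, e) for e in np.eye(core.n)])
    assert np.abs(dense - cols).max() < 1e-8


def test_mixed_blocks_match_gradient_fd(qed_point):
    core, U, eta, dressed, rng = qed_point
    no = core.n_occ
    nv = core.n - no
    xk = rng.standard_normal((nv, no))
    xe = rng.standard_normal(core.n)
    mk, me = lt_mixed(core, dressed, U, xk, xe)
    h = 1e-4
    # eta <- kappa: FD of the eta gradient along the orbital rotation
    gp = eta_gradient(core, dressed, core.density(apply_kappa(U, h * xk, no)))
    gm = eta_gradient(core, dressed, core.density(apply_kappa(U, -h * xk, no)))
    assert np.abs(me - (gp - gm) / (2 * h)).max() < 1e-6
    # kappa <- eta: FD of the kappa gradient along the eta displacement
    kp = kappa_gradient(core, dress_integrals(core, eta + h * xe), U)
    km = kappa_gradient(core, dress_integrals(core, eta - h * xe), U)
    assert np.abs(mk - (kp - km) / (2 * h)).max() < 1e-6


def test_action_linearity_and_symmetry(qed_point):
    core, U, eta, dressed, rng = qed_point
    for blocks in [("kk", "ee"), ("kk", "ee", "mixed")]:
        act = HessianAction(core, dressed, U, blocks_enabled=blocks)
        z1 = rng.standard_normal(act.dim)
        z2 = rng.standard_normal(act.dim)
        lin = act.apply(0.3 * z1 + 1.7 * z2)
        assert np.abs(lin - 0.3 * act.apply(z1)
                      - 1.7 * act.apply(z2)).max() < 1e-10
        assert float(z2 @ act.apply(z1)) == pytest.approx(
            float(z1 @ act.apply(z2)), abs=1e-8)


def test_block_structure_zero_eta_part(qed_point):
    """With mixed blocks off, a pure-kappa trial leaves the eta output zero."""
    core, U, eta, dressed, rng = qed_point
    act = HessianAction(core, dressed, U, blocks_enabled=("kk", "ee"))
    z = np.zeros(act.dim)
    z[:act.nk] = rng.standard_normal(act.nk)
    out = act.apply(z)
    assert np.abs(out[act.nk:]).max() == 0.0


def test_kk_preconditioner_reduces_to_rhf_diagonal(water_sto):
    """At lambda=0 the diagonal is the standard 4(F_aa - F_ii) RHF form."""
    system, ints, rhf = water_sto
    cav0 = CavityConfig(omega=0.5, lambda_coupling=0.0,
                        polarization=np.array([0.0, 0.0, 1.0]))
    core = QEDCore(ints, cav0, 10)
    U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
    d = dress_integrals(core, core.d_diag)
    diag = kk_diagonal_preconditioner(core, d, U0, floor=1e-12)
    eps = rhf.mo_energy
    no = core.n_occ
    ref = 4.0 * (eps[no:, None] - eps[None, :no])
    assert np.abs(diag - ref).max() < 1e-6


def test_preconditioner_entries_floored(qed_point):
    core, U, eta, dressed, rng = qed_point
    pk = kk_diagonal_preconditioner(core, dressed, U, floor=1e-3)
    assert pk.min() >= 1e-3
    pe = eta_diagonal_preconditioner(core, dressed, core.density(U))
    assert pe.min() > 0.0


def test_dense_eta_eta_psd_at_minimum(water_sto):
    """At a converged minimum the eta-eta block has no negative curvature."""
    from polariton_scf.optimizers import run_tr_nr

    system, ints, _ = water_sto
    cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                       polarization=np.array([0.0, 0.0, 1.0]))
    st, rep = run_tr_nr(system, cav, ints=ints)
    assert rep.converged
    d = dress_integrals(st.core, st.eta)
    H = build_dense_eta_eta(st.core, d, st.core.density(st.U)).matrix
    assert np.linalg.eigvalsh(H).min() >= -1e-8


def test_preconditioner_saves_micro_iterations(water_631):
    """On water/6-31G the block-preconditioned Newton solver needs fewer
    Hessian-vector products than the unpreconditioned one."""
    from polariton_scf.optimizers import (TrustRegionState,
                                          solve_trust_region_step)
    from polariton_scf.qed import kappa_gradient, eta_gradient

    system, ints, rhf = water_631
    cav = CavityConfig(omega=0.099592, lambda_coupling=0.005,
                       polarization=np.array([0.0, 0.0, 1.0]))
    core = QEDCore(ints, cav, system.n_electrons)
    U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
    eta0 = core.d_diag.copy()
    dressed = dress_integrals(core, eta0)
    act = HessianAction(core, dressed, U0)
    g = act.join(kappa_gradient(core, dressed, U0),
                 eta_gradient(core, dressed, core.density(U0)))
    kw = dict(tol=1e-8, max_micro=100)
    _, _, m_prec, _ = solve_trust_region_step(
        act, g, TrustRegionState(radius=0.5), act.block_preconditioner(),
        **kw)
    _, _, m_plain, _ = solve_trust_region_step(
        act, g, TrustRegionState(radius=0.5), None, **kw)
    assert m_prec < m_plain


def test_offdiagonal_structure_of_eta_block(qed_point):
    """The eta-eta block carries substantial off-diagonal weight, the
    documented reason plain gradient steps on eta converge poorly."""
    core, U, eta, dressed, rng = qed_point
    H = build_dense_eta_eta(core, dressed, core.density(U)).matrix
    off = H - np.diag(np.diag(H))
    assert np.linalg.norm(off) > 0.1 * np.linalg.norm(H)
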