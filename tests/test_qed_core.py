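"""Dipole basis, dressed integrals, energy, Fock matrix and gradients."""

import math

import numpy as np
import pytest

from polariton_scf.fixtures import h2, water
from polariton_scf.integrals import fetch_ao_integrals
from polariton_scf.qed import (QEDCore, apply_kappa, build_dipole_basis,
                               dress_integrals, eta_gradient,
                               fock_dipole_basis, kappa_gradient,
                               scqed_energy)
from polariton_scf.rhf import run_rhf
from polariton_scf.system import CavityConfig


class TestDipoleBasis:
    def test_invariants(self, water_sto):
        system, ints, rhf = water_sto
        cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                           polarization=np.array([0.0, 0.0, 1.0]))
        db = build_dipole_basis(rhf.mo_coeff, ints, cav)
        n = db.V.shape[0]
        assert np.abs(db.V.T @ db.V - np.eye(n)).max() < 1e-10
        # V^T (d.eps)_MO V diagonal
        dm = -np.einsum("k,kpq->pq", cav.polarization, ints.dipole_e)
        dmo = rhf.mo_coeff.T @ dm @ rhf.mo_coeff
        dtil = db.V.T @ dmo @ db.V
        off = dtil - np.diag(np.diag(dtil))
        assert np.abs(off).max() < 1e-10
        assert np.all(np.diff(db.d_tilde_diag) >= -1e-12)  # ascending
        assert np.allclose(np.diag(dtil), db.d_tilde_diag, atol=1e-10)

    def test_rejects_nonorthonormal(self, water_sto):
        _, ints, rhf = water_sto
        cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                           polarization=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="orthonormal"):
            build_dipole_basis(2.0 * rhf.mo_coeff, ints, cav)

    def test_h2_two_level(self):
        """H2 along the bond axis: eigenvalues symmetric about the midpoint
        dipole, reproduced by an independent 2x2 diagonalization."""
        import scipy.linalg

        sys2 = h2(0.74)
        ints = fetch_ao_integrals(sys2)
        cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                           polarization=np.array([0.0, 0.0, 1.0]))
        core = QEDCore(ints, cav, 2)
        dm = -ints.dipole_e[2]
        w_ref = scipy.linalg.eigh(dm, ints.overlap, eigvals_only=True)
        assert np.allclose(core.d_diag, w_ref, atol=1e-12)
        mid = -0.5 * (sys2.coords[0, 2] + sys2.coords[1, 2])
        assert np.mean(core.d_diag) == pytest.approx(mid, abs=1e-10)

    def test_deterministic_sign_fix(self, water_sto):
        _, ints, _ = water_sto
        cav = CavityConfig(omega=0.5, lambda_coupling=0.05,
                           polarization=np.array([0.0, 0.0, 1.0]))
        c1 = QEDCore(ints, cav, 10).coeff
        c2 = QEDCore(ints, cav, 10).coeff
        assert np.array_equal(c1, c2)
        for j in range(c1.shape[1]):
            assert c1[np.argmax(np.abs(c1[:, j])), j] > 0


class TestDressing:
    def test_zero_coupling_identity(self, qed_point, water_sto):
        _, ints, _ = water_sto
        cav0 = CavityConfig(omega=0.5, lambda_coupling=0.0,
                            polarization=np.array([0.0, 0.0, 1.0]))
        core0 = QEDCore(ints, cav0, 10)
        rng = np.random.default_rng(7)
        d = dress_integrals(core0, rng.standard_normal(core0.n))
        assert np.array_equal(d.h_eta, core0.h)
        assert np.array_equal(d.g_eta, core0.g)

    def test_equal_eta_one_electron_factors(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        d = dress_integrals(core, np.full(core.n, 1.7))
        assert np.array_equal(d.W1, np.ones((core.n, core.n)))

    def test_factors_in_unit_interval(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        assert dressed.W1.max() <= 1.0 and dressed.W1.min() > 0.0
        ratio = np.abs(dressed.g_eta) <= np.abs(core.g) + 1e-15
        assert ratio.all()

    def test_scalar_exponent_spot_check(self, qed_point):
        """One element equals h * exp(-lambda^2 (eta_p - eta_q)^2 / 4 omega)."""
        core, U, eta, dressed, rng = qed_point
        p, q = 1, 4
        fac = math.exp(-core.lam ** 2 * (eta[p] - eta[q]) ** 2
                       / (4.0 * core.omega))
        assert dressed.h_eta[p, q] == pytest.approx(core.h[p, q] * fac,
                                                    rel=1e-12)
        r, s = 3, 0
        S = eta[p] - eta[q] + eta[r] - eta[s]
        fac2 = math.exp(-core.lam ** 2 * S ** 2 / (4.0 * core.omega))
        assert dressed.g_eta[p, q, r, s] == pytest.approx(
            core.g[p, q, r, s] * fac2, rel=1e-12)

    def test_symmetry_of_dressed_tensors(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        assert np.abs(dressed.h_eta - dressed.h_eta.T).max() < 1e-14
        g = dressed.g_eta
        for perm in [(1, 0, 3, 2), (2, 3, 0, 1)]:
            assert np.abs(g - g.transpose(perm)).max() < 1e-12


class TestEnergyAndGradients:
    def test_zero_coupling_matches_rhf(self, water_sto):
        system, ints, rhf = water_sto
        cav0 = CavityConfig(omega=0.5, lambda_coupling=0.0,
                            polarization=np.array([0.0, 0.0, 1.0]))
        core = QEDCore(ints, cav0, 10)
        U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
        d = dress_integrals(core, core.d_diag)
        e = scqed_energy(core, d, core.density(U0))
        assert e == pytest.approx(rhf.energy, abs=1e-10)
        # gradients vanish at the RHF solution, independent of eta machinery
        assert np.abs(kappa_gradient(core, d, U0)).max() < 1e-8
        assert np.abs(eta_gradient(core, d, core.density(U0))).max() < 1e-12

    def test_occ_occ_rotation_invariance(self, qed_point):
        """The energy depends only on the occupied space, not on which
        occupied orbitals span it."""
        core, U, eta, dressed, rng = qed_point
        no = core.n_occ
        A = rng.standard_normal((no, no))
        A = A - A.T
        import scipy.linalg

        R = np.eye(core.n)
        R[:no, :no] = scipy.linalg.expm(A)
        e1 = scqed_energy(core, dressed, core.density(U))
        e2 = scqed_energy(core, dressed, core.density(U @ R))
        assert e2 == pytest.approx(e1, abs=1e-10)

    def test_fock_is_density_derivative(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        D = core.density(U)
        F = fock_dipole_basis(core, dressed, D)
        assert np.abs(F - F.T).max() < 1e-10
        dD = rng.standard_normal((core.n, core.n))
        dD = dD + dD.T
        h = 1e-4
        num = (scqed_energy(core, dressed, D + h * dD)
               - scqed_energy(core, dressed, D - h * dD)) / (2 * h)
        assert num == pytest.approx(float(np.sum(F * dD)), abs=1e-6)

    def test_eta_gradient_fd(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        D = core.density(U)
        g = eta_gradient(core, dressed, D)
        h = 1e-4
        for r in [0, 2, core.n - 1]:
            e = np.zeros(core.n)
            e[r] = 1.0
            fd = (scqed_energy(core, dress_integrals(core, eta + h * e), D)
                  - scqed_energy(core, dress_integrals(core, eta - h * e), D)
                  ) / (2 * h)
            assert g[r] == pytest.approx(fd, abs=1e-6)

    def test_kappa_gradient_fd(self, qed_point):
        core, U, eta, dressed, rng = qed_point
        g = kappa_gradient(core, dressed, U)
        no, nv = core.n_occ, core.n - core.n_occ
        h = 1e-4
        for (a, i) in [(0, 0), (1, 3), (nv - 1, no - 1)]:
            dk = np.zeros((nv, no))
            dk[a, i] = h
            ep = scqed_energy(core, dressed,
                              core.density(apply_kappa(U, dk, no)))
            em = scqed_energy(core, dressed,
                              core.density(apply_kappa(U, -dk, no)))
            assert g[a, i] == pytest.approx((ep - em) / (2 * h), abs=1e-6)

    def test_eta_gradient_zero_at_zero_coupling(self, water_sto):
        _, ints, rhf = water_sto
        cav0 = CavityConfig(omega=0.7, lambda_coupling=0.0,
                            polarization=np.array([0.0, 0.0, 1.0]))
        core = QEDCore(ints, cav0, 10)
        rng = np.random.default_rng(3)
        eta = rng.standard_normal(core.n)
        d = dress_integrals(core, eta)
        U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
        assert np.abs(eta_gradient(core, d, core.density(U0))).max() == 0.0
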