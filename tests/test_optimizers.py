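"""DIIS, trust-region step solver, convergence metrics, and the drivers."""

import math
from dataclasses import dataclass

import numpy as np
import pytest

from polariton_scf.fixtures import water
from polariton_scf.optimizers import (ConvergenceReport, DIISBuffer,
                                      TrustRegionState, convergence_metrics,
                                      diis_extrapolate, run_gb_dbi,
                                      run_gb_diis, run_tr_nr,
                                      solve_trust_region_step)
from polariton_scf.system import CavityConfig, RunConfig


class TestDIIS:
    def test_single_vector_unchanged(self):
        buf = DIISBuffer(5)
        p = np.array([1.0, 2.0, 3.0])
        buf.push(p, np.array([0.1, 0.0, 0.0]))
        assert np.array_equal(diis_extrapolate(buf), p)

    def test_empty_buffer_error(self):
        with pytest.raises(ValueError, match="empty"):
            diis_extrapolate(DIISBuffer(5))

    def test_two_vector_closed_form(self):
        """Matches the hand-solved 2x2 least-squares system.

        With errors e1, e2 the coefficients are
        c1 = (e2.e2 - e1.e2) / (e1.e1 - 2 e1.e2 + e2.e2), c2 = 1 - c1.
        """
        buf = DIISBuffer(5)
        p1, p2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        e1, e2 = np.array([0.3, -0.1]), np.array([-0.2, 0.05])
        buf.push(p1, e1)
        buf.push(p2, e2)
        b11, b12, b22 = e1 @ e1, e1 @ e2, e2 @ e2
        c1 = (b22 - b12) / (b11 - 2 * b12 + b22)
        ref = c1 * p1 + (1 - c1) * p2
        assert np.allclose(diis_extrapolate(buf), ref, atol=1e-12)

    def test_coefficients_sum_to_one(self):
        """Extrapolation of constant parameter vectors is exact (sum c_i = 1)."""
        rng = np.random.default_rng(5)
        buf = DIISBuffer(6)
        const = np.array([3.14, -2.72])
        for _ in range(4):
            buf.push(const, rng.standard_normal(2))
        assert np.allclose(diis_extrapolate(buf), const, atol=1e-8)

    def test_ring_buffer_truncation(self):
        buf = DIISBuffer(3)
        for k in range(7):
            buf.push(np.array([float(k)]), np.array([1.0 / (k + 1)]))
        assert len(buf) == 3


@dataclass
class _MatrixAction:
    M: np.ndarray

    def apply(self, z):
        return self.M @ z


class TestTrustRegionStep:
    def test_identity_returns_negative_gradient(self):
        g = np.array([0.1, -0.2, 0.05])
        act = _MatrixAction(np.eye(3))
        trust = TrustRegionState(radius=1.0)
        step, mu, micro, _ = solve_trust_region_step(act, g, trust, tol=1e-12)
        assert np.allclose(step, -g, atol=1e-10)
        assert mu == 0.0

    def test_matches_dense_solve(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((8, 8))
        H = A @ A.T + 0.5 * np.eye(8)
        g = rng.standard_normal(8)
        trust = TrustRegionState(radius=100.0)
        step, mu, micro, _ = solve_trust_region_step(
            _MatrixAction(H), g, trust, tol=1e-10, max_micro=50)
        assert mu == 0.0
        assert np.abs(step - np.linalg.solve(H, -g)).max() < 1e-8

    def test_boundary_solution_on_radius(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((6, 6))
        H = A @ A.T
        g = rng.standard_normal(6)
        trust = TrustRegionState(radius=0.05)
        step, mu, micro, _ = solve_trust_region_step(
            _MatrixAction(H), g, trust, tol=1e-10, max_micro=50)
        assert np.linalg.norm(step) <= trust.radius + 1e-8
        assert mu > 0.0

    def test_indefinite_direction_shifted_positive(self):
        """The returned shift makes H + mu I positive along probed vectors."""
        H = np.diag([-0.5, 0.2, 1.0, 3.0])
        g = np.array([0.1, 0.3, -0.2, 0.05])
        trust = TrustRegionState(radius=0.5)
        step, mu, micro, _ = solve_trust_region_step(
            _MatrixAction(H), g, trust, tol=1e-10, max_micro=50)
        assert mu >= 0.5 - 1e-6
        rng = np.random.default_rng(2)
        for _ in range(5):
            v = rng.standard_normal(4)
            assert v @ (H @ v) + mu * (v @ v) > -1e-10


class TestMetrics:
    def test_identical_energies_zero_delta(self):
        de, gmax, gk, ge = convergence_metrics(-1.5, -1.5,
                                               np.zeros((2, 3)), np.zeros(5))
        assert de == 0.0 and gmax == 0.0

    def test_first_iteration_sentinel(self):
        de, *_ = convergence_metrics(-1.5, None, np.ones((2, 3)), np.ones(5))
        assert math.isnan(de)

    def test_scaled_norm_definitions(self):
        gk = np.full((2, 3), 2.0)   # N_kappa = 6, |gk|_2 = 2 sqrt(6)
        ge = np.full(4, -1.0)       # N_eta = 4, |ge|_2 = 2
        de, gmax, gkn, gen = convergence_metrics(-1.0, -2.0, gk, ge)
        assert de == 1.0
        assert gmax == 2.0
        assert gkn == pytest.approx(2.0 * math.sqrt(6) / 6)
        assert gen == pytest.approx(0.5)


CAV = CavityConfig(omega=0.099592, lambda_coupling=0.005,
                   polarization=np.array([0.0, 0.0, 1.0]))


class TestDrivers:
    @pytest.mark.parametrize("driver", [run_gb_diis, run_tr_nr, run_gb_dbi])
    def test_zero_coupling_reproduces_rhf(self, driver, water_sto):
        system, ints, rhf = water_sto
        cav0 = CavityConfig(omega=0.5, lambda_coupling=0.0,
                            polarization=np.array([0.0, 0.0, 1.0]))
        st, rep = driver(system, cav0, ints=ints)
        assert rep.converged
        assert st.energy == pytest.approx(rhf.energy, abs=1e-9)

    def test_cross_algorithm_agreement(self, water_sto):
        system, ints, _ = water_sto
        st1, r1 = run_tr_nr(system, CAV, ints=ints)
        st2, r2 = run_gb_dbi(system, CAV, ints=ints)
        assert r1.converged and r2.converged
        assert abs(st1.energy - st2.energy) < 1e-9
        assert np.abs(np.sort(np.abs(st1.eta))
                      - np.sort(np.abs(st2.eta))).max() < 1e-6

    def test_determinism(self, water_sto):
        system, ints, _ = water_sto
        st1, r1 = run_tr_nr(system, CAV, ints=ints)
        st2, r2 = run_tr_nr(system, CAV, ints=ints)
        assert r1.n_macro == r2.n_macro
        assert np.array_equal(r1.energies, r2.energies)
        assert st1.energy == st2.energy

    def test_tr_nr_descent_and_exit_thresholds(self, water_sto):
        system, ints, _ = water_sto
        cfg = RunConfig(algorithm="tr_nr")
        st, rep = run_tr_nr(system, CAV, cfg, ints=ints)
        assert rep.converged
        e = rep.energies
        assert np.all(np.diff(e) <= 1e-12)   # accepted steps lower the energy
        assert rep.records[-1].max_grad <= cfg.gradient_threshold

    def test_report_lengths(self, water_sto):
        system, ints, _ = water_sto
        cfg = RunConfig(algorithm="gb_diis", max_iterations=5)
        st, rep = run_gb_diis(system, CAV, cfg, ints=ints)
        assert not rep.converged           # 5 iterations cannot suffice
        assert rep.n_iterations == 5
        assert rep.n_macro == 5

    def test_gb_dbi_stationary_exit(self, water_sto):
        system, ints, _ = water_sto
        cfg = RunConfig(algorithm="gb_dbi")
        st, rep = run_gb_dbi(system, CAV, cfg, ints=ints)
        assert rep.converged
        assert rep.records[-1].max_grad <= cfg.gradient_threshold

    def test_mixed_blocks_same_stationary_point(self, water_sto):
        """Enabling the mixed Hessian blocks changes the path, not the
        answer."""
        system, ints, _ = water_sto
        st1, r1 = run_tr_nr(system, CAV, ints=ints)
        st2, r2 = run_tr_nr(system, CAV,
                            RunConfig(algorithm="tr_nr",
                                      use_mixed_blocks=True), ints=ints)
        assert r1.converged and r2.converged
        assert abs(st1.energy - st2.energy) < 1e-9

    def test_log_line_machine_parsable(self, water_sto):
        system, ints, _ = water_sto
        st, rep = run_tr_nr(system, CAV, ints=ints)
        line = rep.records[-1].log_line()
        assert "E=" in line and "max|E1|=" in line and "micro=" in line
        log = rep.log()
        assert log.count("\n") == rep.n_iterations
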