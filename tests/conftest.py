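import numpy as np
import pytest

from polariton_scf.fixtures import water
from polariton_scf.integrals import fetch_ao_integrals
from polariton_scf.qed import QEDCore, apply_kappa, dress_integrals
from polariton_scf.rhf import run_rhf
from polariton_scf.system import CavityConfig


@pytest.fixture(scope="session")
def water_sto():
    """Water/STO-3G: (system, integrals, RHF result)."""
    system = water("sto-3g")
    ints = fetch_ao_integrals(system)
    rhf = run_rhf(ints, system.n_electrons)
    assert rhf.converged
    return system, ints, rhf


@pytest.fixture(scope="session")
def water_631():
    system = water("6-31g")
    ints = fetch_ao_integrals(system)
    rhf = run_rhf(ints, system.n_electrons)
    assert rhf.converged
    return system, ints, rhf


@pytest.fixture(scope="session")
def qed_point(water_sto):
    """A recorded non-stationary point for derivative tests.

    Water/STO-3G at lambda=0.05, omega=0.5 with a fixed orbital rotation and
    a fixed eta displacement away from the dipole eigenvalues.
    """
    system, ints, rhf = water_sto
    cavity = CavityConfig(omega=0.5, lambda_coupling=0.05,
                          polarization=np.array([0.0, 0.0, 1.0]))
    core = QEDCore(ints, cavity, system.n_electrons)
    U0 = core.coeff.T @ ints.overlap @ rhf.mo_coeff
    rng = np.random.default_rng(20240930)
    eta = core.d_diag + 0.1 * rng.standard_normal(core.n)
    dk = 0.05 * rng.standard_normal((core.n - core.n_occ, core.n_occ))
    U = apply_kappa(U0, dk, core.n_occ)
    dressed = dress_integrals(core, eta)
    return core, U, eta, dressed, rng
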