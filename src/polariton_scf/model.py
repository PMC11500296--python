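"""Model/results interface for SC-QED-HF calculations.

:class:`SCQEDHF` bundles a molecule with a cavity; :meth:`SCQEDHF.fit`
runs one of the SCF drivers and returns an :class:`SCQEDHFResults` carrying
the converged state, the per-iteration convergence report, diagnostics and
a ``summary()`` table.  Checkpointing (HDF5) and the heat-map diagnostic of
the Hessian blocks hang off the results object.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .hessian import (HessianAction, build_dense_eta_eta,
                      lt_kappa_kappa)
from .integrals import AOIntegralSet, fetch_ao_integrals
from .optimizers import ConvergenceReport, run_scf
from .qed import (QEDCore, SCQEDState, build_dipole_basis, dress_integrals,
                  eta_gradient, fock_dipole_basis, kappa_gradient)
from .system import CavityConfig, MolecularSystem, RunConfig, read_xyz
from .units import HARTREE_TO_EV


class SCQEDHF:
    """Strong-coupling QED Hartree-Fock model for one molecule + cavity.

    Parameters
    ----------
    system : MolecularSystem
    cavity : CavityConfig
    run_config : RunConfig, optional
        Default driver settings; can be overridden per ``fit`` call.

    Examples
    --------
    >>> from polariton_scf import SCQEDHF
    >>> from polariton_scf.fixtures import water
    >>> model = SCQEDHF(water("sto-3g"), omega_ev=2.71, coupling=0.01)
    >>> res = model.fit(method="tr_nr")
    >>> print(res.summary())           # doctest: +SKIP
    """

    def __init__(self, system: MolecularSystem,
                 cavity: CavityConfig | None = None,
                 run_config: RunConfig | None = None,
                 omega_ev: float | None = None,
                 coupling: float | None = None,
                 polarization=(0.0, 0.0, 1.0)):
        if cavity is None:
            if omega_ev is None or coupling is None:
                raise ValueError("provide a CavityConfig or omega_ev+coupling")
            cavity = CavityConfig(omega=omega_ev / HARTREE_TO_EV,
                                  lambda_coupling=coupling,
                                  polarization=np.asarray(polarization, float))
        self.system = system
        self.cavity = cavity
        self.run_config = run_config or RunConfig()
        self._ints: AOIntegralSet | None = None

    @classmethod
    def from_xyz(cls, path, charge=0, basis="sto-3g", **kwargs) -> "SCQEDHF":
        return cls(read_xyz(path, charge=charge, basis_name=basis), **kwargs)

    @property
    def integrals(self) -> AOIntegralSet:
        if self._ints is None:
            self._ints = fetch_ao_integrals(self.system)
        return self._ints

    def fit(self, method: str | None = None, initial=None,
            **overrides) -> "SCQEDHFResults":
        """Optimize the SC-QED-HF wave function.

        ``method`` is one of ``gb_diis``, ``tr_nr`` (default), ``gb_dbi``;
        keyword overrides are applied on top of the model's run
        configuration (e.g. ``max_iterations=500``).
        """
        cfg = self.run_config
        if method is not None:
            overrides = {"algorithm": method, **overrides}
        if overrides:
            cfg = replace(cfg, **overrides)
            cfg.__post_init__()
        driver_kwargs = {"ints": self.integrals}
        if initial is not None:
            driver_kwargs["initial"] = initial
        state, report = run_scf(self.system, self.cavity, cfg,
                                **driver_kwargs)
        return SCQEDHFResults(self, state, report, cfg)


class SCQEDHFResults:
    """Converged (or terminated) SC-QED-HF state with diagnostics."""

    def __init__(self, model: SCQEDHF, state: SCQEDState,
                 report: ConvergenceReport, cfg: RunConfig):
        self.model = model
        self.state = state
        self.report = report
        self.run_config = cfg
        self.converged = report.converged
        self.energy = state.energy
        self.eta = state.eta
        core = state.core
        self.core: QEDCore = core
        self.mo_coeff = state.mo_coeff
        dressed = dress_integrals(core, state.eta)
        self._dressed = dressed
        D = core.density(state.U)
        F = fock_dipole_basis(core, dressed, D)
        self.orbital_energies = np.sort(np.diag(state.U.T @ F @ state.U))
        self.g_kappa = kappa_gradient(core, dressed, state.U)
        self.g_eta = eta_gradient(core, dressed, D)
        self.dipole_basis = build_dipole_basis(self.mo_coeff,
                                               model.integrals, model.cavity)

    # -- diagnostics ---------------------------------------------------
    def dense_eta_eta(self) -> np.ndarray:
        return build_dense_eta_eta(self.core, self._dressed,
                                   self.core.density(self.state.U)).matrix

    def eta_hessian_offdiagonal_mass(self) -> float:
        """Fraction of the eta-eta Hessian's Frobenius weight off-diagonal.

        The eta-eta block is strongly non-diagonal for typical molecules,
        which is why plain gradient descent on eta stagnates.
        """
        H = self.dense_eta_eta()
        total = float(np.linalg.norm(H)) ** 2
        if total == 0:
            return 0.0
        return 1.0 - float(np.linalg.norm(np.diag(H))) ** 2 / total

    def dense_kappa_kappa(self) -> np.ndarray:
        """Explicit kappa-kappa block via the linear transformation."""
        core = self.core
        nk = (core.n - core.n_occ) * core.n_occ
        cols = []
        for j in range(nk):
            e = np.zeros(nk)
            e[j] = 1.0
            cols.append(lt_kappa_kappa(
                core, self._dressed, self.state.U,
                e.reshape(core.n - core.n_occ, core.n_occ)).ravel())
        return np.column_stack(cols)

    def export_hessian_heatmap(self, prefix, kk_cutoff: float = 5.0,
                               ee_cutoff: float = 20.0) -> list[str]:
        """Write Hessian block grids (.txt) and a heat-map figure (.png).

        Color scales are clipped at the given cutoffs so the off-diagonal
        structure of the eta-eta block stays visible next to the diagonally
        dominant kappa-kappa block.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        prefix = str(prefix)
        Hee = self.dense_eta_eta()
        Hkk = self.dense_kappa_kappa()
        written = []
        for name, H in (("kk", Hkk), ("ee", Hee)):
            np.savetxt(f"{prefix}_{name}.txt", H)
            written.append(f"{prefix}_{name}.txt")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (name, H, cut) in zip(
                axes, [("kappa-kappa", Hkk, kk_cutoff),
                       ("eta-eta", Hee, ee_cutoff)]):
            im = ax.imshow(np.clip(np.abs(H), 0.0, cut), cmap="viridis")
            ax.set_title(name)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(f"{prefix}.png", dpi=120)
        plt.close(fig)
        written.append(f"{prefix}.png")
        return written

    def plot_convergence(self, path=None):
        """Per-iteration |dE|, max|E1| and scaled gradient norms."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        recs = self.report.records
        it = [r.iteration for r in recs]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.semilogy(it, [max(r.delta_e, 1e-18) for r in recs], "o-",
                    label=r"$|\Delta E|$")
        ax.semilogy(it, [max(r.max_grad, 1e-18) for r in recs], "s-",
                    label=r"max $|E^{(1)}|$")
        ax.semilogy(it, [max(r.kappa_norm_scaled, 1e-18) for r in recs],
                    "^-", label=r"$\|g_\kappa\|_2/N_\kappa$")
        ax.semilogy(it, [max(r.eta_norm_scaled, 1e-18) for r in recs],
                    "v-", label=r"$\|g_\eta\|_2/N_\eta$")
        ax.set_xlabel("iteration")
        ax.legend()
        ax.set_title(f"{self.report.algorithm} convergence")
        fig.tight_layout()
        if path is not None:
            fig.savefig(str(path), dpi=120)
            plt.close(fig)
            return str(path)
        return fig

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        sysm = self.model.system
        cav = self.model.cavity
        lines = [
            "SC-QED-HF results",
            "=" * 64,
            f"molecule             {'/'.join(sysm.atoms)}  "
            f"charge={sysm.charge}  basis={sysm.basis_name}",
            f"cavity               omega = {cav.omega:.6f} Ha "
            f"({cav.omega * HARTREE_TO_EV:.3f} eV), lambda = "
            f"{cav.lambda_coupling}, eps = {np.round(cav.polarization, 6)}",
            f"algorithm            {self.report.algorithm}",
            f"converged            {self.converged}",
            f"macro-iterations     {self.report.n_macro}",
            f"micro-iterations     {self.report.total_micro_iterations} "
            f"(mean {self.report.mean_micro_iterations:.2f}/macro)",
            f"total energy         {self.energy:.12f} Ha",
            f"max |E^(1)|          "
            f"{max(np.abs(self.g_kappa).max(initial=0.0), np.abs(self.g_eta).max(initial=0.0)):.3e}",
            f"HOMO / LUMO          "
            f"{self.orbital_energies[self.core.n_occ - 1]:.6f} / "
            + (f"{self.orbital_energies[self.core.n_occ]:.6f} Ha"
               if self.core.n_occ < self.core.n else "n/a"),
            f"eta range            [{self.eta.min():.6f}, "
            f"{self.eta.max():.6f}]",
        ]
        return "\n".join(lines)

    # -- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        """Write an HDF5 checkpoint sufficient to restart any optimizer."""
        import h5py

        with h5py.File(str(path), "w") as f:
            f.attrs["energy"] = self.energy
            f.attrs["converged"] = self.converged
            f.attrs["algorithm"] = self.report.algorithm
            f.attrs["n_macro"] = self.report.n_macro
            f.attrs["basis"] = self.model.system.basis_name
            f.attrs["charge"] = self.model.system.charge
            f.attrs["omega"] = self.model.cavity.omega
            f.attrs["lambda"] = self.model.cavity.lambda_coupling
            f.create_dataset("U", data=self.state.U)
            f.create_dataset("eta", data=self.eta)
            f.create_dataset("mo_coeff", data=self.mo_coeff)
            f.create_dataset("dipole_orbitals", data=self.core.coeff)
            f.create_dataset("polarization",
                             data=self.model.cavity.polarization)
            f.create_dataset("atoms",
                             data=np.array(self.model.system.atoms, dtype="S4"))
            f.create_dataset("coords", data=self.model.system.coords)


def load_checkpoint(path) -> dict:
    """Read a checkpoint back into plain arrays + metadata."""
    import h5py

    out = {}
    with h5py.File(str(path), "r") as f:
        out.update({k: f.attrs[k] for k in f.attrs})
        for k in f.keys():
            out[k] = np.asarray(f[k])
    if "atoms" in out:
        out["atoms"] = [a.decode() for a in out["atoms"]]
    return out
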