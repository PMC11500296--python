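"""Molecular systems, cavity parameters and run configuration.

All quantities are stored in atomic units; XYZ files are Angstrom and the
cavity frequency is accepted in eV, converted on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .elements import atomic_number
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, EV_TO_HARTREE


@dataclass
class MolecularSystem:
    """A molecule: element symbols, coordinates (bohr), total charge."""

    atoms: list[str]
    coords: np.ndarray
    charge: int = 0
    basis_name: str = "sto-3g"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for a in self.atoms:
            atomic_number(a)  # validates symbols
        if self.n_electrons <= 0:
            raise ValueError("system has no electrons")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"{self.n_electrons} electrons: only closed-shell (even "
                "electron count) references are supported"
            )

    @property
    def n_electrons(self) -> int:
        return sum(atomic_number(a) for a in self.atoms) - self.charge

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([atomic_number(a) for a in self.atoms], dtype=float)

    def translated(self, shift) -> "MolecularSystem":
        """Copy of the system rigidly translated by ``shift`` (bohr)."""
        return MolecularSystem(
            atoms=list(self.atoms),
            coords=self.coords + np.asarray(shift, float),
            charge=self.charge,
            basis_name=self.basis_name,
        )


@dataclass
class CavityConfig:
    """Single effective cavity mode: frequency (hartree), coupling, polarization."""

    omega: float
    lambda_coupling: float
    polarization: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self):
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.omega <= 0:
            raise ValueError("cavity frequency must be positive")
        if self.lambda_coupling < 0:
            raise ValueError("coupling strength must be non-negative")
        n = np.linalg.norm(self.polarization)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"polarization vector has norm {n}, expected 1")
        if abs(n - 1.0) > 1e-12:
            self.polarization = self.polarization / n


_ALGORITHMS = ("gb_diis", "tr_nr", "gb_dbi")


@dataclass
class RunConfig:
    """SCF driver selection and thresholds (all deterministic)."""

    algorithm: str = "tr_nr"
    energy_threshold: float = 1e-10
    gradient_threshold: float = 1e-10
    max_iterations: int = 200
    diis_dim: int = 8
    trust_radius_init: float = 0.5
    micro_tolerance: float = 1e-6
    micro_max: int = 100
    eta_step: float = 0.1          # gb-DIIS steepest-descent step for eta
    use_mixed_blocks: bool = False

    def __post_init__(self):
        alg = self.algorithm.replace("-", "_").lower()
        if alg not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {_ALGORITHMS}")
        self.algorithm = alg
        if self.energy_threshold <= 0 or self.gradient_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def read_xyz(path, charge: int = 0, basis_name: str = "sto-3g") -> MolecularSystem:
    """Read a standard XYZ file (count line, comment, 'El x y z' in Angstrom)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: first line is not an atom count") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise ValueError(f"{path}: header declares {n} atoms, found {len(body)}")
    atoms, coords = [], []
    for ln in body[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        atoms.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return MolecularSystem(
        atoms=atoms,
        coords=np.array(coords) * ANGSTROM_TO_BOHR,
        charge=charge,
        basis_name=basis_name,
    )


def write_xyz(system: MolecularSystem, path, comment: str = "") -> None:
    """Write the system as a standard XYZ file (Angstrom)."""
    lines = [str(len(system.atoms)), comment]
    for sym, xyz in zip(system.atoms, system.coords * BOHR_TO_ANGSTROM):
        lines.append(f"{sym:<3s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> tuple[MolecularSystem, CavityConfig, RunConfig]:
    """Load a YAML run configuration.

    Required keys: geometry (path to XYZ, relative to the config file),
    basis, coupling, frequency_ev, polarization.  Optional: charge,
    algorithm, energy_threshold, gradient_threshold, max_iterations,
    diis_dim, trust_radius_init, eta_step, use_mixed_blocks.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    for key in ("geometry", "basis", "coupling", "frequency_ev", "polarization"):
        if key not in raw:
            raise KeyError(f"{path}: missing required config key {key!r}")
    geom = Path(raw["geometry"])
    if not geom.is_absolute():
        geom = path.parent / geom
    system = read_xyz(geom, charge=int(raw.get("charge", 0)),
                      basis_name=str(raw["basis"]))
    cavity = CavityConfig(
        omega=float(raw["frequency_ev"]) * EV_TO_HARTREE,
        lambda_coupling=float(raw["coupling"]),
        polarization=np.asarray(raw["polarization"], dtype=float),
    )
    run_keys = {f.name for f in RunConfig.__dataclass_fields__.values()}
    run = RunConfig(**{k: v for k, v in raw.items() if k in run_keys})
    return system, cavity, run
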