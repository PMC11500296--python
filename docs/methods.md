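# Methods

## Model

The light–matter system is the length-gauge Pauli–Fierz Hamiltonian in the
dipole approximation with one effective cavity mode,

    H = H_el + ω b†b − λ √(ω/2) (d·ε)(b + b†) + (λ²/2)(d·ε)²,

with H_el the usual electronic Hamiltonian, d = d^e + d^nuc the molecular
dipole operator, ε a unit polarization vector, ω the mode frequency
(hartree internally; eV at the input boundary) and λ the coupling in
atomic units.  The sign of the bilinear term is a gauge choice (b → −b);
the spectrum and all observables are unaffected.

All orbital-resolved quantities live in the **dipole basis**: the basis
diagonalizing the polarization-projected dipole operator.  Because that
diagonalization is a generalized eigenproblem over the AO space,
(d·ε)_AO c = ε̃ S c, the dipole-basis orbitals are a *fixed* property of
the molecule, basis set and polarization — they do not depend on the
current SCF orbitals.  We exploit this: the dipole-basis one- and
two-electron integrals are transformed once per calculation, and an SCF
state is just the pair (U, η) with U the orthogonal matrix expressing the
canonical orbitals in the dipole basis.  The orthogonal matrix connecting
the current MOs to the dipole basis (the V of the working equations) is
recovered as V = CᵀSC̃ whenever needed.  Degenerate dipole eigenvalues are
ordered deterministically by the symmetric eigensolver and a fixed sign
convention (largest-magnitude AO coefficient positive), so repeated runs
are bit-identical and no re-association of η between iterations ever
arises.

### Ansatz and energy

The SC-QED-HF ansatz applies an orbital-specific coherent-state
(polaron-like) transformation to a closed-shell determinant times the
photon vacuum,

    |ψ⟩ = exp( (λ/√(2ω)) Σ_p η_p Ẽ_pp (b† − b) ) |HF⟩ ⊗ |0⟩,

one displacement amplitude η_p per spatial orbital.  The sign convention
is fixed so that η_p → d̃_pp (the dipole eigenvalues) as λ → ∞, where the
ansatz becomes exact.  Taking the photon expectation values analytically
— the step that keeps the method at mean-field cost, with no photonic
Hilbert space ever represented in the production code — gives

    E(D̃, η) = Σ_pq h̃_pq W¹_pq D̃_pq
             + ½ Σ_pqrs g̃_pqrs W²_pqrs (D̃_pq D̃_rs − ½ D̃_ps D̃_rq)
             + (λ²/2) ⟨(d·ε − Σ_p η_p Ẽ_pp)²⟩ + E_nuc,

with Gaussian dressing factors

    W¹_pq   = exp(−γ (η_p − η_q)²),
    W²_pqrs = exp(−γ (η_p − η_q + η_r − η_s)²),     γ = λ²/(4ω).

The factors lie in (0, 1], reduce to 1 at λ = 0 or equal η, and inherit
the permutational symmetries of the integrals.  The cavity expectation
value expands over the one- and two-particle closed-shell densities; its
minimizing η absorbs the molecular dipole, which is what makes the
converged energy of a charged system origin independent (a uniform η
shift of (a·ε)Q_tot/N_e compensates a translation a — only translations
with a component along ε couple at all).

Because the equation layer of the source material was not machine-readable
in this workspace, every assembled expression is pinned by independent
oracles rather than by transcription alone: analytic gradients and all
Hessian blocks are verified against central finite differences of the
energy at recorded non-stationary points (h = 1e-4, agreement ≤ 1e-6,
typically 1e-10), the λ = 0 limit is checked against a separate textbook
AO-basis RHF, and the variational property is checked against an exact
diagonalization of the same Hamiltonian in a (determinant) ⊗ (photon
number) basis for H2.

### Derivatives

The energy depends on the orbitals only through D̃, so the SC-QED Fock
matrix F̃ = ∂E/∂D̃ (dressed one-electron part, dressed Coulomb/exchange,
and a cavity contribution) generates the κ-gradient as 4·(UᵀF̃U)_ai in the
canonical frame; the η-gradient collects the derivative of the dressing
factors (−4γ-weighted contractions of η-difference-weighted dressed
integrals with the densities) plus the cavity term.  Hessian-vector
products are expressed through gradient-like contractions of transformed
quantities, never through explicit rank-4 Hessian tensors:

- κκ: a one-index-transformed Fock commutator plus the response Fock of
  the rotated density (the response map reuses the dressed integrals via
  BLAS matrix–vector products over the reshaped N²×N² tensor);
- ηη: contractions of (1 − 2γS²)-weighted dressed integrals; because the
  block is only N×N it is also assembled densely once per outer iteration
  and applied by matmul (the matrix-free transformation is kept as an
  independent code path and the two are cross-checked on the full unit
  basis);
- mixed κη/ηκ blocks: implemented and tested, disabled by default — they
  cost roughly another two-electron pass per product and do not reduce
  the iteration count enough to pay for themselves.

## Optimizers

All three drivers start from the cavity-free RHF orbitals with η
initialized at the dipole eigenvalues d̃_pp, and share the convergence
metrics: |ΔE|, max |E⁽¹⁾| over the joint gradient, and the L²-norms of
the κ- and η-gradients scaled by the parameter counts (N_κ = n_occ·n_virt,
N_η = N_orb).  Convergence requires |ΔE| and max |E⁽¹⁾| below their
thresholds (both 1e-10 a.u. by default).  Everything is deterministic.

**gb-DIIS** (baseline): Roothaan–Hall diagonalization of F̃ with DIIS on
the Fock matrix (error [F̃, D̃]; subspace 8), and a damped steepest-descent
η step (default 0.1, configurable — the stagnation behaviour depends on
it) accelerated by DIIS with g_η as the error vector.  On harder systems
the scaled η-gradient plateaus orders of magnitude above threshold while
the energy creeps by ~1e-13/iteration; the per-iteration report exposes
exactly this plateau.

**tr-NR**: one joint Newton step per macro-iteration on (κ ⊕ η) — Δκ
applied through the orbital exponential map and Δη additively,
simultaneously.  The level-shifted equations (H + μI)Δz = −g (μ ≥ 0 is
the Levenberg–Marquardt damping, the negative of the level shift written
with a minus sign in the usual quantum-chemistry convention) are solved in
a Davidson-type subspace: μ = 0 when the unshifted Newton step is interior
and the subspace Hessian positive definite, otherwise μ is found by root
search on ‖Δz(μ)‖ = radius in the subspace eigenbasis.  Micro-iterations
count Hessian-vector products; the residual target is
min(1e-2·‖g‖, 1e-6) (inexact-Newton forcing), capped at 100 products.
The preconditioner is block-structured: the Fock-difference diagonal
4(F_aa − F_ii) (floored at 1e-3) for κ, and the *exact* shifted inverse of
the dense η–η block for η — with the mixed blocks disabled the Hessian is
exactly block diagonal, so this leaves the solver only the diagonally
dominant κκ part and keeps the mean micro-iteration count in single
digits.  Trust-radius policy: initial 0.5; shrink ×0.7 on gain ratio
< 0.25, ×0.5 with rejection on an energy increase (beyond a 1e-13-scale
roundoff slack), expand ×2 after a well-predicted boundary-limited step
(up to 32).  The doubling expansion replaces a slower 1.2 growth factor:
the η parameters typically travel a distance of O(5–20) from their
initialization at weak coupling, and a slowly growing radius keeps the
optimizer boundary-limited past ten iterations without any accuracy
benefit.

**gb-DBI**: the gb-DIIS density update, but η is updated by a Newton step
from the direct inversion of the dense η–η block (eigendecomposition with
eigenvalues floored at 1e-8; while the block has a negative eigenvalue —
which happens in the first iterations of difficult cases — a damped
gradient step is taken instead).  No micro-iterations at all.

## Oracles and fixtures

The validation module is implementationally independent of the production
paths: the finite-difference oracle only calls the public energy; the
Fock-space oracle builds the Pauli–Fierz Hamiltonian with its own
second-quantization algebra over determinant bit strings (≤ 80
determinants, i.e. H2-in-a-minimal-basis scale) tensored with a photon
number basis (cutoff n_max, converged when successive increments change
the ground state by < 1e-10; n_max = 10–12 suffices at the couplings
tested).  Fixture geometries (H2 0.74 Å; water 0.9572 Å/104.52°; ammonia
1.0116 Å/106.7°; formaldehyde r_CO 1.208 Å, r_CH 1.116 Å, HCH 116.5°;
tetrahedral NH4+ 1.024 Å) are standard equilibrium values generated in
code; iteration-count benchmarks test the convergence class of the
algorithms, which is robust to small geometry differences.

The integral engine was validated against closed-form two-center results
and published RHF energies (H2/STO-3G −1.1167 at R = 1.4 bohr, H2O/6-31G
−75.98400, H2O/aug-cc-pVDZ −76.04143, CH4/aug-cc-pVDZ −40.19962,
CH2O/aug-cc-pVDZ −113.88463) and by rigid-motion invariance tests.  Basis
tables are plain-text NWChem-format files with H/C/N/O entries.

## Problem sizes and numerical choices

Full N⁴ two-electron tensors are held in memory up to 200 basis functions;
beyond that the run aborts with a message pointing at the (unimplemented)
Cholesky-batching hook.  The benchmark calculation (formaldehyde,
aug-cc-pVDZ, 64 spherical orbitals) runs in about a minute on one CPU;
cross-algorithm and invariance checks use STO-3G/6-31G fixtures to keep
the full suite fast.  Dressed-integral caches (the N²×N² reshapes for
Coulomb/exchange, the η-weighted tensors for Hessians) are built lazily
per η and discarded with the dressing object.  The Boys function uses a
downward-recursion series below T = 35 and the erf closed form with upward
recursion above.  RHF convergence for the initial orbitals is 1e-12 in the
energy and 1e-8 in the DIIS error, tight enough that the λ = 0 reduction
holds to 1e-9.

## What the tests do and do not show

The suite establishes internal consistency (all derivatives against
finite differences, dense vs matrix-free Hessians, cross-algorithm
agreement to 1e-9 hartree, determinism), exactness of limits (λ = 0,
infinite-coupling sign convention), the variational bound against exact
diagonalization on a two-electron system, origin invariance for a charged
ion together with the frozen-η ablation that visibly breaks it, and the
documented convergence-class behaviour of the three optimizers on
desk-scale molecules.  They do not benchmark wall time, do not cover
open-shell references, multimode or chiral cavities, and do not validate
basis-set completeness for chemical predictions — the embedded tables
cover H, C, N, O only.
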