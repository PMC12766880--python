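# Methods

This note records the model, the numerical conventions, and the design
choices behind `rdmvqe`, in the order the pipeline runs.

## Electronic-structure layer

**Integrals.** A built-in McMurchie–Davidson engine supplies every STO-3G
integral over contracted Cartesian Gaussians (s and p shells for H and C):
overlap, kinetic, nuclear attraction, electron repulsion, dipole, and
nuclear-attraction-type integrals at arbitrary points for the exact
electrostatic potential. Hermite Coulomb integrals are built iteratively
from a single Boys-function evaluation per primitive quartet (series +
downward recursion below x = 35, asymptotic + upward recursion above); the
two-electron tensor has a numba-compiled kernel, cross-checked in the test
suite against the pure-python reference to 10⁻¹³. Positions are Å at the
user surface and Bohr internally; energies are Hartree; dipoles are
converted with 1 a.u. = 2.541746473 D.

**RHF.** Closed-shell restricted Hartree–Fock with DIIS (error vector
FDS − SDF, 8-vector window), convergence 10⁻¹¹ Eh on the energy. The
converged `SCFReference` bundles C, S, h, (μν|λσ), dipole integrals, and
γ^HF; everything downstream reads only this container, so the
mathematical core is independent of the integral provider. Serialization
uses a single `.npz` file with named arrays.

**Active space.** The (n_e, n_o) window takes the n_e/2 highest occupied
and the remaining lowest virtual canonical MOs; lower occupied MOs are
frozen at double occupation (explicit index override available; a warning
is logged when the orbital-energy gap at a window edge is below 10⁻⁸ Eh).
Frozen orbitals are folded with the standard inactive-Fock expressions
h^eff_pq = h_pq + Σ_i [2(pq|ii) − (pi|iq)] and
E_core = E_nuc + Σ_i 2h_ii + Σ_ij [2(ii|jj) − (ij|ji)]. The folded
Hamiltonian round-trips through FCIDUMP so the VQE stack and the CI
reference consume bit-identical integrals.

**Qubit mapping.** Jordan–Wigner with two frozen conventions: interleaved
spin orbitals (α₀, β₀, α₁, β₁, …) and qubit 0 as the leftmost tensor
factor (most significant bit of the basis index). Pauli terms with
|coefficient| < 10⁻¹² are pruned; Hermiticity is asserted by requiring
real coefficients to 10⁻¹⁰.

## Ansätze and gradients

Every gate is exp(θK) with K the real antisymmetric matrix of a fermionic
excitation generator; K³ = −K, so gates apply in closed form
(I + sinθ·K + (1−cosθ)·K²) and dU/dθ = KU gives machine-precision
adjoint gradients (cross-checked against central finite differences at
h = 10⁻⁵ for every circuit shape).

* **k-UpCCGSD**: per layer, all generalized spin-conserving singles over
  spatial pairs (p, q), p < q, in lexicographic order (α before β within
  a pair), then all paired doubles p̄p → q̄q in the same pair order. The
  ordering defines the circuit and is frozen. (2,2) → 3 parameters per
  layer; (4,4) → 18.
* **GateFabric**: brick-wall of 4-qubit tiles over neighboring orbital
  pairs (even layers start at orbital 0, odd at orbital 1; with only two
  orbitals every layer is the single tile). Each tile applies a paired
  DoubleExcitation(θ) then an OrbitalRotation(φ) — two same-angle Givens
  rotations, one per spin — for 2 parameters per tile. No fixed Π block
  by default, so θ = 0 prepares exactly the HF bitstring; the Π-block
  variant (a full Givens swap per tile before the parameterized gates) is
  available as `include_pi=True`.

Both families conserve particle number and S_z structurally (the sparse
generators never leave the particle-number sector, so the variance of N̂
on any prepared state is exactly zero).

## 1-RDM measurement and embedding

The active 1-RDM is assembled exclusively from Hermitian Pauli
observables: diagonals from (I − ⟨Z_p⟩)/2, off-diagonal real/imaginary
parts from (X_pX_q + Y_pY_q)/4 and (X_pY_q − Y_pX_q)/4 with JW Z-strings
on intervening qubits, lower triangle by Hermitian conjugation. Both
parts are always measured even though the shipped ansätze have real
generators; the spin-sum to the spatial matrix discards an imaginary
residue only after checking it is below 10⁻⁸ (a larger residue raises).

Embedding into the molecule: a full-MO matrix with 2 on the
frozen-occupied diagonal, the measured block on the active window, zero
elsewhere (no correlation is assigned outside the window), transformed to
AO by γ = C D C†. With the HF occupation pattern in the active block this
reproduces γ^HF exactly, and trace(γS) equals the electron count for any
trace-preserving active block.

## The three optimization loops

All variants are full-batch gradient descent with a fixed step (default
0.4) from θ₀ = 0; there is no stochastic element anywhere, so identical
configurations give bitwise-identical trajectories. Per iteration the
loop records E, |ΔE|, ΔD, w_D, ‖G_E‖, ‖G_D‖, and θ.

* ΔD uses the spin-summed spatial matrix with N = n_active_orbitals by
  default (the spin-orbital normalization differs only by a bounded
  factor and is exposed as a config switch).
* w_D = f·‖G_E‖/‖G_D‖ is recomputed every iteration from the current
  gradients and is zero on the first iteration (no G_D yet) and whenever
  ‖G_D‖ = 0. With f = 0, VQE-LD reduces exactly — bitwise — to plain VQE
  updates.
* G_D differentiates ΔD(θ) with D(n−1) as a constant reference:
  ∇ΔD = ∇⟨A⟩ / (ΔD·N²) where A = Σ_pq (D−D_prev)*_pq Ê_pq is a fixed
  Hermitian observable rebuilt each iteration. The square root is not
  differentiable at ΔD = 0; below 10⁻¹⁴ the safeguarded subgradient
  G_D = 0 is used.
* Exit: plain VQE stops at |ΔE| < E_tol (ΔD is recorded but not
  enforced); VQE*/VQE-LD require |ΔE| < E_tol and ΔD < D_tol on the same
  iteration. The first iteration never terminates (no predecessor), and
  hitting `max_iterations` (default 5000) flags the result non-converged
  instead of raising.

Defaults follow the study settings: E_tol = D_tol = 10⁻⁶, learning rate
0.4, f = 0.05 for k-UpCCGSD (0.1 at R = 1.8) and f = 0.7 / 0.9 for the
two GateFabric geometries.

## CASCI reference

Brute-force determinant CI over (α, β) occupation bitmask pairs with
N_α = N_β, Slater–Condon matrix elements with chemists' integrals, and
the α-block-before-β-block sign convention, verified against dense
diagonalization of the JW qubit Hamiltonian to 10⁻¹⁰ on random
8-fold-symmetric integrals. Dense eigensolve below 2000 determinants,
Lanczos above. The CI 1-RDM comes from single-excitation connections with
the same phase bookkeeping, and the CI vector can be loaded as a JW
statevector (permutation parity from reordering the α/β blocks into
interleaved order) — the cross-module identity measure(ci_statevector) =
ci_one_rdm holds to 10⁻¹⁰ and anchors the measurement apparatus.

## Properties

Density, gradient, and Hessian are analytic contractions of Gaussian
derivatives; the Laplacian is the Hessian trace (no numerical
differencing anywhere in production paths). The ESP's electronic term
contracts γ with point-charge one-electron integrals (exact, not
quadrature); grid points within 10⁻⁶ Bohr of a nucleus are masked.
Critical points: Newton iteration (trust radius 0.5 Bohr) seeded at every
nucleus and at midpoints of atom pairs within 4.5 Bohr — the cutoff is
set so the long C–H contacts of the stretched geometries (≈ 4.0 Bohr at
R = 2.1 Å) are still seeded — converged to ‖∇ρ‖ < 10⁻¹⁰, deduplicated
within 10⁻⁴ Bohr, and discarded below ρ = 10⁻⁴ (far-field artifacts).
Classification is by Hessian signature with the standard QTAIM
convention: NCP = three negative eigenvalues (a density maximum), BCP =
two negative one positive. BCPs are attached to the two nuclei their
bond path reaches (steepest ascent along the positive-curvature
eigenvector), which correctly distinguishes the long C1–H contact from
the nearby H–H bond. Ring and cage points are reported as "other" and
not analyzed. Cube export uses the standard Gaussian layout (Bohr,
z-fastest, six values per line) at 0.10 Bohr resolution over the
molecule's bounding box padded by 4 Bohr; dipoles default to the
coordinate origin of the supplied geometry, with an explicit origin
override.

## Packaged CH₅⁺ geometries

The five structures are synthetic stand-ins, generated once by relaxing a
Cs-symmetric parametrization (mirror pair H5/H6; in-plane H2, H3, H4; the
H3–H4 midpoint clamped at distance R from the carbon) at frozen-core
CISD/STO-3G using this package's own RHF + determinant-CI machinery, then
shifted to the center-of-mass frame. That frame choice makes the default
dipole origin the center of mass — the natural reference for a cation
whose dissociation coordinate is itself mass-weighted. Consequences worth
knowing: the CASCI(4,4) total energies at these structures agree with
published values for the same R to ~10⁻⁴–10⁻³ Eh, and origin-sensitive
properties (the total dipole of the +1 ion, Mulliken charges) agree to a
few 10⁻² — geometry-bound decimals are not reproduced exactly. All
*method-contrast* quantities (energy errors between variants, ΔD
behavior, step-count ordering, dipole-error improvements, the NCP/BCP
topology) are computed method-vs-method on identical geometries and are
insensitive to the stand-in.

## Known limitations

* Fixed-step gradient descent with zero initialization can stall in local
  basins on strongly correlated problems: for the linear H₄ chain fixture
  the k = 2 UpCCGSD circuit is variationally exact, but no fixed learning
  rate between 0.05 and 0.4 (nor VQE-LD up to f = 1) reaches the global
  minimum from θ₀ = 0. This is a property of the optimization protocol,
  kept deliberately faithful to the study conditions.
* Our GateFabric (2,2) landscape for CH₅⁺ is benign: plain VQE reaches
  the active-space variational limit in a few steps, so the package
  demonstrates the ΔD-tolerance contrast (energy-only stopping leaves
  ΔD ≈ 10⁻⁵; the density-aware variants drive it below 10⁻⁶) but not a
  catastrophic plain-VQE energy failure.
* Closed-shell RHF only; JW mapping only; no shot noise or hardware noise
  models; two-particle RDMs are never computed (no algorithm here needs
  them).
* Problem sizes: determinant CI is dense-diagonalized up to 2000
  determinants (the study needs at most 36); statevectors up to 8 qubits.
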