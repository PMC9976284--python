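# Methods

This note documents the models, conventions and numerical choices behind
`resoraman`, and what the synthetic test systems do and do not show
about real chromophore/environment data.

## Units and conventions

Coordinates are stored in Å and converted to Bohr only at module
boundaries (one conversion site, to avoid unit drift); masses are stored
in amu and converted to electron masses before mass-weighting, so
mass-weighted Hessian eigenvalues are in Hartree·mₑ⁻¹·Bohr⁻² and convert
to wavenumbers as ν̃ = sign(λ)·√|λ|/(2πc).  All conversion factors are
derived from CODATA constants via `scipy.constants` at import time, so
every pair composes to identity to machine precision; the photon
conversion uses hc = 1239.84198 eV·nm.  Imaginary frequencies are
encoded as negative wavenumbers (the common quantum-chemistry
convention) and are data, not errors: snapshots are not stationary
points.  Mode "reduced masses" follow the μ = (Σ l²_cart)⁻¹ convention
of the mainstream engines, where l_cart = M^(−1/2)L with L the
mass-weighted-orthonormal eigenvector.

Hessians are exchanged in a bespoke plain-text format (header
`hessian <N> <unit-tag>`, then 3N rows of 3N floats, Hartree/Bohr²):
there is no standard interchange format for Cartesian Hessians, and
plain text keeps fixtures diff-able.  Asymmetry up to 1e-6 relative is
silently symmetrized, up to 1e-3 with a warning, beyond that it is an
error.

## The four normal-mode strategies

**A0** diagonalizes the snapshot Hessian directly, optionally after
Eckart projection of the 3 translations and 3 (2 if linear, detected by
moment-of-inertia rank) infinitesimal rotations.  Projection at a
non-stationary geometry is formally ill-defined (the gradient is
nonzero), so both paths are exposed; the projected null-space modes are
dropped when their residual wavenumbers are below 1 cm⁻¹ in magnitude
(configurable), otherwise an error advises review.

**PHVA** diagonalizes the 3Nₐ×3Nₐ active-atom sub-block of the
mass-weighted Hessian, which is exactly the infinite-environment-mass
limit.  No Eckart projection is applied by default because the frozen
environment breaks translational/rotational invariance; an opt-in flag
projects the active-subsystem rigid motions only.  With the full atom
set and projection off, PHVA reproduces A0 identically (tested to
1e-8 cm⁻¹).

**A1** computes the weighted least-squares rigid transform (Kabsch, via
SVD of the weighted covariance) of a reference structure onto each
frame, with the reflection branch disabled (det forced +1), and rotates
every atomic displacement of every reference mode by the fitted
rotation.  Weights default to unity — mass-weighted fitting is a flag —
and atom correspondence is by file order.  The rotated vectors are *not*
re-orthogonalized against the frame's translation/rotation space: the
operation is a pure rotation, which preserves mass-weighted
orthonormality exactly.  For a degenerate (collinear) reference the spin
about the molecular axis is resolved by the smallest total rotation
angle.

**A2** removes user-declared soft torsions from the harmonic treatment.
Each proper dihedral (IUPAC sign convention, φ = atan2(|b₂|·b₁·(b₂×b₃),
(b₁×b₂)·(b₂×b₃))) is linearized as its analytic Wilson B row, verified
in the suite against central finite differences and against the exact
orthogonality to rigid translations and rotations.  The projection is
performed in mass-weighted Cartesian space — the linearized realization
of "projecting out" a coordinate, exact for infinitesimal displacements
(a curvilinear treatment would differ at finite amplitude, a known
limitation).  The soft vectors uᵢ = M^(−1/2)Bᵢᵀ are orthonormalized
together with the translation/rotation vectors by modified Gram–Schmidt
with one re-orthogonalization pass and a rank tolerance of 1e-8 (a
dependent soft coordinate is reported by label); P = I − Σ|u⟩⟨u| is then
applied on both sides of the mass-weighted Hessian and the 6+m smallest
|ν̃| modes dropped under the same < 1 cm⁻¹ sanity check.  Cauchy
interlacing guarantees the surviving eigenvalues stay within the
original spectral range; the suite asserts this on random symmetric
matrices.  Choosing *which* torsions are soft is left to the user; the
imaginary-mode report supports the workflow of selecting torsions
implicated in imaginary modes.

## Clustering and snapshot handling

Pairwise RMSD is minimized over rigid superposition (heavy atoms by
default) and fed to greedy neighbor-count clustering: repeatedly take
the frame with the most neighbors within the cutoff (ties broken by
lowest index) as a representative, remove its neighborhood, repeat.
Persistence = cluster size / total frames; these fractions weight the
per-representative spectra in the final average.  The cutoff default is
1.0 Å and is data-dependent — cluster counts on real trajectories are
descriptive output, not targets.  The solvent-shell cut is residue
level: a residue is kept if any of its atoms is within the cutoff of any
target atom, so no molecule is ever split.  Input frames are assumed to
contain whole (unwrapped) molecules.

## RR intensities

The short-time approximation is used throughout: stick intensities are
built from geometric derivatives of the complex frequency-dependent
polarizability, with the electronic damping Γ (default 500 cm⁻¹) passed
*into* the calculator as part of the complex frequency argument rather
than applied as post-processing.  Derivatives are central differences
with step 0.001 in mass-weighted atomic units (Bohr·√mₑ) along each
real mode — the convention of the engines this protocol targets; the
step is exposed so a Cartesian-Bohr interpretation can be reproduced.
Imaginary modes are excluded from RR evaluation and logged.
Antisymmetric polarizability components (possible at resonance) are
rejected rather than silently symmetrized, because the invariant
formulas a̅² = |tr d/3|² and γ̅² = ½Σ|dᵢᵢ−dⱼⱼ|² + 3Σ|dᵢⱼ|² assume a
symmetric tensor.

The cross-section prefactor uses the standard differential Stokes form
(ν̃₀−ν̃_k)³·ν̃₀ with activity 45a̅²+7γ̅² and the 1/ν̃_k factor from the
normal-coordinate normalization.  Because every spectrum is
max-normalized, all constant prefactors cancel and only the frequency
factors matter.  The thermal occupancy factor [1−exp(−hcν̃/k_BT)]⁻¹ is
off by default (flag to enable); anti-Stokes lines and modes at or above
the incident energy are skipped with a warning.  Broadening is a
unit-area Lorentzian of HWHM 10 cm⁻¹ (FWHM 20 cm⁻¹); convolution is
linear, so convolving per representative and then averaging with
persistence weights equals the reverse order — normalization to unit
maximum is applied last, once, on the average.  No frequency scaling is
applied by default (`freq_scale` option available).  The default
spectral grid is 1000–2000 cm⁻¹ at 1 cm⁻¹.

## The synthetic test systems

`toy_models` generates everything the suite and the acceptance script
consume; no external data or electronic-structure engine is needed.

*Molecules* are built by spectral synthesis: a seeded non-collinear
geometry, a random mass-weighted-orthonormal basis orthogonal to
translation/rotation, and the Hessian M^(1/2)L·diag(λ)·LᵀM^(1/2) whose
diagonalization must return the prescribed wavenumbers — an exact oracle
for every vibrational code path, including imaginary and degenerate
spectra.

*Polarizabilities* come from a sum-over-states pole model
α(ω) = Σ μⱼ⊗μⱼ[(Eⱼ−ħω−iΓ)⁻¹ + (Eⱼ+ħω+iΓ)⁻¹] with geometry-dependent
Eⱼ(q); the chain-rule derivative is available in closed form, the oracle
for finite-difference convergence.  The default test model makes the
excitation energy linear in exactly one normal coordinate
(0.02 eV per Bohr·√mₑ around 2.49 eV), so one mode dominates the RR
spectrum — a sharp, predictable signal analogous to the enhancement of
modes coupled to a bright electronic transition.

*Trajectories* draw independent Gaussian mass-weighted normal
coordinates with the classical equipartition variance ⟨Q²⟩ = k_BT/ω²
(classical sampling matches the classical-MD provenance of real
snapshots), mapped to Cartesian, with optional uniform random rigid
rotations per frame to exercise A1.  Default toy conditions: 5 atoms,
9 modes spanning 400–1900 cm⁻¹, 20 frames at 50 K (small-amplitude
regime where the harmonic picture is exact); the strategy-concordance
checks run at 0.5 K, i.e. the T→0 limit in which all four strategies
must agree.

What these fixtures do **not** emulate: anharmonicity (the toy Hessian
is exactly constant, so snapshot Hessians never acquire genuine
imaginary curvature — tests that need imaginaries construct them
explicitly), conformational multi-modality beyond synthetic blobs,
vibronic structure beyond a few poles, and environment polarization.
Passing tests certify the algorithmic machinery — projections,
superposition, derivatives, weighting — not the electronic-structure
quality of any real application, which enters solely through the
user-supplied polarizability calculator and Hessians.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; the run manifest echoes
all parameters and re-running from it reproduces outputs bit-exactly.
The validation script (`scripts/acceptance.py`) uses deliberately small
problems — 5-atom toys, 40-frame clustering sets, 2·10⁵ brute-force
rotation samples, 3-frame end-to-end runs — chosen so the full
recomputation finishes in seconds while still exercising every stage
against an independent oracle.

## Known limitations

- Soft coordinates are proper dihedrals only (bonds/angles not
  implemented); the linear projector is exact only infinitesimally.
- The A0 Eckart projection at non-stationary geometries is a convention,
  not a theorem; both projected and unprojected paths are exposed.
- The Kabsch degenerate-spectrum tie-break (smallest rotation angle) is
  exercised only for collinear inputs; planar degeneracies fall back to
  the SVD's choice.
- Snapshot Hessians must be supplied (or generated); the package
  performs no electronic-structure computation itself.
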