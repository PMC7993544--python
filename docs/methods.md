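# Methods

## Conductivity PDE

The phase-based MREPT equation assumes σ_H ≫ ωε_H (valid for tissue at
≥ 3 T) and that the transceive phase approximates twice the transmit phase.
The stabilized form

−c∇²τ_H + ∇φ^tr·∇τ_H + τ_H∇²φ^tr = 2ωμ₀,  τ_H = 1/σ_H

is discretized with central differences for both ∇ and ∇² on the voxel grid
(anisotropic spacing supported); the artificial diffusion c is the only
stabilizer — no upwinding — matching the mechanism the formula relies on.
All spatial derivatives are taken in meters so σ_H lands in S/m and the
conventional c values (0.02–1) apply verbatim; the equation scales uniformly
with length units, so expressing spacing in mm with consistent derivatives
changes nothing.

Choices the formulation leaves open, resolved as follows:

* **Boundary condition.** Dirichlet τ_H on a 2-voxel band along the mask
  edge, set to the reciprocal of the band-averaged pointwise estimate
  σ ≈ ∇²φ^tr/(2ωμ₀). If pre-smoothing has invalidated the band (see below),
  the averaging collar widens inward until it contains valid estimates.
* **Pre-smoothing.** At realistic phase SNR the discrete Laplacian of raw
  phase is noise-dominated (second differences divide by h² ≈ 10⁻⁶ m²), and
  the resulting linear system can be numerically singular. An optional
  Gaussian pre-filter (`smooth_sigma`, in voxels; default off) is applied to
  the phase entering both the boundary estimate and the PDE coefficients.
  Noise-free simulations run unsmoothed and recover quadratic-phase
  solutions exactly.
* **Linear solve.** Sparse direct (SuperLU) below 40k unknowns, otherwise
  ILU-preconditioned LGMRES. The relative residual must reach 1e-8 or the
  solver raises. Voxels with recovered τ_H ≤ 0 are excluded from the valid
  mask and counted.
* **ω default** 2π × 128 MHz (3 T); `PdeConfig.at_field_strength` derives
  ω = γB₀ for other field strengths (the vesicle phantom protocol runs at
  9.4 T, but conductivity recovery is ω-independent once the phase is
  consistent, so simulations default to 3 T).

The stabilization length √(c/(2ωμ₀σ)) is ≈ 5 mm at c = 0.05 and σ = 1 S/m.
Region-mean accuracy therefore requires regions large against this length:
synthetic phantoms default to 2 mm voxels on a 48×48×24 grid with a ~26 mm
inclusion, recovering two-region means within ~1.5% at c ∈ {0.02, 0.05}.
Total variation of σ_H decreases monotonically in c on fixed noisy input —
the low-pass action of the diffusion term.

## Three-pool diffusion model

Direction-averaged normalized signal:
S_b/S₀ = f_ic(f_in·A_in + f_is·A_is) + f_ec·A_ec, with f_ic + f_ec = 1 and
f_in + f_is = 1. Assumptions inherited from the model family: no exchange
between pools, no CSF/free-water pool, orientation effects removed by the
powder average, soma modelled as impermeable spheres under the Gaussian
phase distribution (GPD) approximation.

* A_ec = exp(−b·D_ec).
* A_in = √(π/(4bD_in))·erf(√(bD_in)); limit 1 below bD = 1e-12. Verified
  in tests against a dense numerical sphere average of the oriented stick
  signal (< 0.5% over bD ∈ [0.1, 10]).
* A_is: GPD series over the roots of (x)⁻¹J_{3/2}(x) = J_{5/2}(x)
  (equivalently tan x = 2x/(2−x²), or j₁'(x) = 0; first root 2.0816…).
  Roots are bracketed in ((m−1)π, mπ) and found by Brent's method to 1e-14;
  a residual check against the spherical-Bessel-derivative form guards the
  cache. The prefactor 1/(x²−2) is safe because x₁² > 2. Series truncation
  defaults to M = 50 terms; over the training intervals and both protocol
  timings, M = 50 vs M = 200 moves log A_is by < 1e-8. The free-diffusion
  limit (r_s → large ⇒ A_is → exp(−bD_is)) and the fully-restricted limit
  (r_s → 0 ⇒ A_is → 1) are exercised in tests.
* Gradient amplitude from b via the pulsed-gradient spin-echo relation
  b = γ²G²δ²(Δ − δ/3), γ = 2.6752×10⁸ rad·s⁻¹·T⁻¹, G in T/mm, b in s/mm²,
  diffusivities in mm²/s, r_s stored in mm (reported in µm).
* D_is is fixed at 2×10⁻³ mm²/s and never regressed, to control the
  ill-posedness of the six-parameter problem.

## Random-forest inversion

The training dictionary is a full Cartesian grid of uniformly spaced values
over f_in, f_ec ∈ [0.01, 0.99], D_in, D_ec ∈ [0.1, 3]×10⁻³ mm²/s,
r_s ∈ [3, 20] µm; the default 13 points per parameter give 371,293 rows.
Features are the direction-averaged normalized signals at the non-zero
shells only (the b = 0 feature is identically 1 and is excluded). Optional
Rician corruption s' = √((s+n₁)²+n₂²) with σ = 1/SNR models magnitude
noise; the training SNR is configurable (50 when noising is requested —
the mid noise case of the phantom study — and noise-free for noise-free
recovery studies). An 80/20 split, multi-output forest, and optional tree-
count selection by held-out MSE over a grid complete the training; all other
hyperparameters stay at scikit-learn defaults, and predictions are clipped
to the training intervals. Everything is deterministic under fixed seeds.

**Problem sizes.** A 300-tree forest on the full 13⁵ dictionary stores
roughly 7 GiB of tree nodes; the package therefore runs its own studies at
reduced sizes chosen for a single-CPU desk machine: 9⁵ rows × 50 trees for
recovery statistics (noise-free held-out Pearson r ≈ 0.91/0.93 for
f_ec/D_ec) and 13⁵ × 50 trees for the end-to-end phantom. Shell matching at
prediction time is exact on b values; a protocol mismatch raises rather than
retraining silently.

## Conductivity decomposition

c̄_ec = σ_H/(β(f_ne·D_in + f_so·D_is) + f_ec·D_ec) with the apparent ion
concentrations absorbing charges, Stokes radii and temperature; c̄_in =
c̄_is = β·c̄_ec with a scalar β (1.0 for the electrolyte vesicle phantom,
0.41 for brain from literature ion-concentration ratios; β is a known
constant-ratio simplification, not a map). The compartment sums close on
σ_H identically — asserted at 1e-12 relative in tests. Voxels with a
non-positive denominator or missing upstream estimates propagate as masked,
never zero-filled. Reports quote c̄ and D on the conventional 10⁻³ mm²/s
scale.

Tensors: D_b is fitted log-linearly at the b = 1000 shell only (higher
shells are reserved for the compartment model); negative eigenvalues are
clamped to a small floor and flagged. The split tensors are scalar multiples
of D_b (shared eigenvectors by construction); the soma tensor is the
closure residual D_b − D_ec − D_ne and is flagged wherever η_ec + η_ne > 1
(model inconsistency between the fitted trace and the microstructure maps —
common where D_ec is overestimated). Eigen-ties are broken by fixing each
eigenvector's largest-magnitude component positive, making glyph tables and
L/T/A summaries deterministic. L = principal eigenvalue, T = mean of the
other two, A = mean of all three, averaged over a region.

## Synthetic phantom

The generator emulates a two-compartment conductivity phantom: an
electrolyte background (0.8 S/m) with a cylindrical inclusion (1.0 S/m)
holding a giant-vesicle suspension — cell-like spheres with thin insulating
membranes, diameters normal with mean 13 µm and sd 4.7 µm (radius
distribution truncated at zero; the generator refuses > 1% non-positive
mass), intracellular fraction 0.425 (equal-volume mixing of vesicles at
~85% packing with electrolyte), hindered extracellular diffusivity
1.4×10⁻³ mm²/s in the suspension and free water 2.0×10⁻³ mm²/s in the
background. DWI protocol: shells 1000/2200/3000/3600 s/mm², 30 directions
(spherical Fibonacci lattice), δ/Δ = 6/53.8 ms. β = 1 because the same
electrolyte fills both spaces.

* **Forward phase**: the divergence form ∇·(τ∇φ) = 2ωμ₀ is solved by finite
  volumes with harmonic face averaging of τ and Dirichlet boundary values
  from the closed-form quadratic phase of the boundary conductivity; for a
  uniform map this reproduces φ = ωμ₀σ(x²+y²+z²)/3 exactly. Using a
  different scheme for the forward problem than the inverse solve keeps the
  round trip non-trivial.
* **Vesicle DWI**: ROI signal f_ec·exp(−bD_ec) + f_ic·⟨A_is(r)⟩ with the
  soma signal averaged over the radius distribution by 64-point
  Gauss–Legendre quadrature (single-radius mode available); isotropic, so
  identical across gradient directions.
* **Noise**: Gaussian with std ⟨S⟩/(√2·SNR). The phase channel adds the
  noise to the real and imaginary parts of a unit-magnitude complex signal
  and re-extracts the phase, re-anchored to the clean value so smooth
  multi-cycle phase fields stay unwrapped. For DWI the realization drawn
  for S₀ is, by convention, re-used for every S_b (`shared_realization`;
  an independent-noise mode exists).
* **Motion**: one phase-encode line per TR; sinusoidal displacement
  modulates each line by exp(−2πik·d(t)/N) — a phase-only k-space operation
  (energy-preserving, identity at amplitude 0) that produces the familiar
  ghost replicas along the phase-encode axis.

What the generator does **not** emulate: coil-dependent B1 magnitude
structure, B0 inhomogeneity and susceptibility effects, eddy-current and
EPI distortions, partial-volume CSF, exchange across membranes, and
orientation dispersion. Passing tests therefore demonstrate correctness of
the computational chain and its noise behaviour, not scanner-data fidelity.

## Known limitations

* **The four-shell inversion is severely ill-conditioned for soma/water
  mixtures without neurites.** A nearest-signal search shows the vesicle
  ROI signal is identifiable in exact arithmetic (the unique parameter
  vector within 2×10⁻³ sup-norm has f_ec ≈ 0.57, the truth), but parameter
  combinations with large stick fractions reproduce it to ~10⁻³. The forest,
  which averages dictionary targets at a resolution far coarser than that,
  returns a volume-weighted mean dominated by stick-rich rows: the
  noise-free ROI-mean f_ec comes out near 0.44 with the 13⁵ dictionary
  (less with coarser ones) instead of 0.575, and the downstream ROI σ_ec
  and c̄_ec inherit the bias. The corresponding end-to-end test asserts the
  controlled range and fails, documenting the estimator's bias rather than
  hiding it. Denser dictionaries monotonically reduce the bias; memory
  bounds the practical density.
* The model has no CSF pool, so σ_ec underestimates σ_H in CSF-rich voxels.
* β is a global scalar; real intra/extracellular concentration ratios vary
  spatially.
* The PDE solution blurs interfaces over the stabilization length; region
  statistics should exclude interface bands (the tests erode 3–4 voxels).
* Sample (n−1) standard deviations are used in all region tables.
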