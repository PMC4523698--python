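# Methods

This note records the model implemented by `vesselvote`, the numerical
choices behind it, what the synthetic phantoms do and do not emulate, and
the known limitations. All symbols follow the field's standard notation
for multi-scale Hessian analysis and tensor voting.

## Scale space and token selection

Gaussian second derivatives are computed separably in physical units
(per-axis voxel sigma = σ/spacing, reflect boundaries) and γ-normalised
with γ = 1, i.e. multiplied by σ², so responses are comparable across the
ladder and the per-voxel argmax defining the optimal-scale image M(**x**)
is well posed. The sampled derivative kernels are moment-corrected
(zeroth moment of the second-derivative kernel forced to 0, second moment
to the exact value): without this, truncation tails of order 1e-4 give a
constant image a nonzero "Hessian" and break the invariance of the
vesselness under intensity offsets. Anisotropic voxels are handled by the
per-axis conversion; volumes are never resampled for analysis.

Eigenvalues are ordered by absolute value, |κ₃| ≥ |κ₂| ≥ |κ₁|, with a
deterministic eigenvector sign (largest-magnitude component positive,
first occurrence on ties). Curvatures smaller than 1e-11 of the volume's
intensity magnitude are treated as zero: γ-normalised |κ| is bounded by
the intensity range, so anything below that is floating-point noise (a
constant volume would otherwise "detect" structure in rounding error).

The vesselness is the smooth tube-likeness family: the three geometric
factors built from R_A = |κ₂|/|κ₃| (plate vs line), R_B = |κ₁|/√|κ₂κ₃|
(blob) and the Frobenius norm S (structureness), each with sensitivities
α = β = 0.5 and c defaulting to half the maximum γ-normalised S over the
whole ladder, and — in the default `manniesing` variant — an extra
smoothness factor exp(−2c_s²/(|κ₂|κ₃²)) that suppresses near-zero
eigenvalue responses continuously (c_s = 10⁻³ · max|κ₃|^{3/2};
the plain three-factor `frangi` variant is available behind the same
interface). ν = 0 wherever κ₂ ≥ 0 or κ₃ ≥ 0 (bright vessels on dark
background; a config flag inverts intensities for dark-vessel inputs).

Argmax ties across scales resolve to the smallest scale, favouring
thin-vessel fidelity. Tokens are the voxels satisfying κ₂ < 0 ∧ κ₃ < 0
at at least one scale; each carries the eigensystem recomputed at its
M(**x**). The pipeline additionally drops tokens whose peak vesselness is
below 5% of the volume maximum (`token_min_nu_rel`): points with very
small eigenvalues carry no structural evidence and behave as noise, and
without the floor background voxels dominate both runtime and, for
isotropic (ball) initialisations, the accumulated field. The bare module
API (`select_tokens`) defaults the floor to 0.

## Token encoding

The spectrum decomposition T = stick + plate + ball is used throughout;
reconstruction is exact to rounding. In the inverse-curvature stick mode,
λᵢ = |κᵢ|⁻¹ keeps the pairing with (v₁, v₂, v₃); the ordering
λ₁ ≥ λ₂ ≥ λ₃ follows from the κ ordering and is asserted rather than
re-sorted. |κ|⁻¹ is capped at 10³ × the median nonzero value over the
token set to keep zero curvatures finite. Intensity saliencies are
clamped non-negative and rescaled to [0, 1] by their 99.9th percentile so
modalities with different intensity units vote at comparable magnitudes.
Structure-tensor gradients are computed at σ = M(**p**) and σ-normalised
(×σ), the γ = 1 convention of the Hessian, so squared-gradient saliencies
are comparable across tokens with different optimal scales.

## Voting

Each voter **q** casts within the spherical reach ‖v‖ ≤ N = 2 M(**q**) mm
(window indexed by the voter; for smoothly varying M this covers the same
pairs as receiver-indexed windows and allows per-scale kernel
precomputation). The per-axis voxel half-width is ⌈N/spacing⌉, minimum 1.

The stick vote is the classic arc connection: voter and receiver joined
by the circular arc tangent to the stick line at the voter; the vote is
rank-1 along the arc-rotated direction (rotation by 2θ in the
stick–displacement plane) with magnitude
exp(−(s² + c κ_arc²)/σ_d²), zero beyond a 45° cutoff between displacement
and stick line. σ_d = N/3, making the straight-line decay at the window
edge e⁻⁹ ≈ 10⁻⁴. The curvature weight defaults to the conventional
coupling c(σ_d) = −16 log(0.1)(σ_d−1)/π², clamped at zero.

Plate and ball votes are orientation averages of stick votes:

* plate — 32 equispaced line orientations in the plate plane, with the
  in-plane basis derived deterministically from the plate normal (so the
  vote is a function of the component, not of an arbitrary eigenbasis);
  equispaced line orientations integrate the self-vote exactly;
* ball — a deterministic 1024-point Fibonacci hemisphere; the
  zero-displacement entry is pinned so the self-vote returns the
  component exactly. At 1024 orientations the quadrature sits within
  ~0.8% of its converged value, verified in the tests against stratified
  Monte-Carlo integration over 10⁴ orientations.

These quadratures are this package's realisation of the standard
closed-form orientation integrals; they were chosen so the ball/plate
kernels are validated by construction against the stick kernel they
integrate, rather than transcribed formulas validated against nothing.

Accumulation is linear: votes sum per voxel into a dense PSD tensor
field, and voting a union of disjoint token sets equals the sum of voting
each set (component saliencies below 1e-12 of a token's trace are treated
as exact zeros — eigh noise on rank-deficient tensors — token-locally, so
linearity is preserved). A brute-force token-by-voxel double loop over
the public per-pair kernels serves as the correctness oracle on small
volumes; production and oracle agree to ~1e-15.

## Analysis and fusion

The accumulated field is eigendecomposed per voxel (λ₁ ≥ λ₂ ≥ λ₃ ≥ 0,
tiny negatives clamped; genuinely non-PSD voxels raise) into the S-map
(λ₁−λ₂, e₁), C-map (λ₂−λ₃, e₃) and J-map (λ₃). λ₁ = s_S + s_C + s_J
holds per voxel. Zero-tensor voxels carry the sentinel direction (0,0,0),
which fusion reads as zero alignment — cosine fusion yields nothing where
either modality found nothing, by design ("punishes discord").

Before fusion each modality's S-map is rescaled to [0, 1] by its 99.9th
percentile, so no modality dominates through units. Maps from modalities
on other grids are resampled onto the first-listed modality's grid by
linear interpolation, directions renormalised afterwards. The cosine
operator, its L-modality form, and min/max baselines are as in the README;
φ_cosine ≤ φ_max voxel-wise, all operators are permutation-symmetric and
monotone in the saliencies.

## Evaluation protocol

Probability maps are mapped to [0, 1] by 99.9th-percentile normalisation
before fuzzy Dice against a binary or probabilistic reference; the
both-empty case returns 1. For binary comparisons the normalised map is
Otsu-thresholded; the comparison harness reports both paths. Consensus
reference masks use a voxel-wise vote with a majority (⌈n/2⌉) default
threshold. False-positive volume of probabilistic maps is compared
threshold-free, as background φ mass per unit vessel φ mass: per-map
auto-thresholds (Otsu) adapt to each map's histogram and hide exactly the
effect being measured, while the relative mass is stable across noise
realisations. No significance test is implemented; tables report
mean ± sd over seeds.

## Phantoms: what they emulate, and what passing tests show

Phantoms render tubes (straight, helical, bifurcating polylines) with a
Gaussian radial profile of sd = radius/2, so the binary truth mask
(distance ≤ radius) sits at two profile sigmas — an idealisation of
partial-volume boundaries. Two default modalities share the geometry and
differ as CTA vs phase-contrast MR differ in practice: point spread
0.2 mm vs 0.5 mm, additive Gaussian noise sd 0.05 vs 0.12 of the unit
tube intensity, on a 48³ grid at 1 mm isotropic. Dropout segments
attenuate stated arclength fractions of a tube to 15% signal in one
modality only; the `dropout_pair` preset gives the two modalities
complementary (disjoint) dropouts. All randomness comes from one seed;
truth masks are noise-invariant.

For scale-recovery experiments, tubes are built with profile sd equal to
the nominal radius (`profile_sd_factor=1`): for a Gaussian ridge of scale
t the γ = 1-normalised response σ²t²/(t²+σ²)² peaks exactly at σ = t, so
these phantoms are the ones with a known correct answer for M(**x**).

The phantoms contain no anatomy: no skull/brain boundary, no bone or
calcification, no flow artefacts, no spatially correlated tissue texture
— the background is iid noise. Passing tests therefore demonstrate the
geometric and algebraic contracts of the method (scale selection,
direction recovery, fusion behaviour under dropouts and discord), not
clinical-grade accuracy; absolute DSC values on phantoms are not
comparable to values on clinical data. Two regime effects observed on
phantoms and worth knowing: (i) isotropic (ball) initialisations infer
orientation purely from the spatial arrangement of tokens, which works
for thin tubes but washes out when the tube cross-section is several
voxels wide (the in-plane token mass competes with the axial coherence) —
the initialisation-comparison suite therefore uses 1.5 mm tubes, the
thin-vessel regime the 1.0–4.5 mm ladder targets; (ii) the
structure-tensor initialisation's small-vessel failure only appears when
large and small vessels share one volume and normalisation, so that check
uses a two-tube phantom (2.0 mm and 0.7 mm radius on a 0.6 mm grid).

## Problem sizes and runtime

Default test problem sizes — 48³ voxels, ten scales, a few thousand
tokens per modality — were chosen so a full two-modality extraction runs
in seconds on one CPU and the whole suite in under two minutes, while
keeping tube diameters and the scale ladder in the regime the method is
designed for. The voting stage dominates; it scales with token count ×
window volume.

## Known limitations

* Historical implementations of the vote kernels differ in minor
  constants; the kernels here are the canonical arc forms validated by
  quadrature and phantom properties rather than transcription.
* Receiver- vs voter-indexed windows differ where M(**x**) varies
  sharply (e.g. at junctions); the voter-indexed choice is implemented.
* The fuzzy-DSC-vs-binary-truth protocol penalises diffuse probabilistic
  maps; ball-family initialisations score low on phantoms for this
  reason even where their ordering is informative.
* Single-pass bright-vessel analysis only; dark-vessel inputs are
  handled by intensity inversion, not a dual pass.
* No registration: inputs must be affinely co-registered upstream.
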