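# Methods

This note documents the models, numerical choices, and limitations of the
toolkit, in the spirit of a model-documentation page: what is simulated and
how, what each metric computes, how the optimizer and the statistics are
configured, and what the synthetic data can and cannot tell you about real
scans.

## CT simulation

**Geometry.** Acquisition is 2-D parallel-beam, applied independently to each
axial slice. The reconstruction grid is a square of `image_size` voxels over
a field of view `fov` (default 256 voxels over 350 mm); the detector row has
pitch equal to the pixel pitch and covers the image diagonal, and projection
angles are uniform over [0, π) (default 512). Parallel-beam geometry was
chosen because it admits exact analytic oracles (chord lengths, adjoint
identities, rotational symmetry) and runs at desk scale; clinical fan-beam or
helical geometry, scatter, beam hardening, and tube-current modulation are
deliberately out of scope.

**Projector.** The forward projector is pixel-driven: each voxel contributes
`value · h²/Δt` (voxel area over detector pitch) to the two detector bins
bracketing its projected coordinate `t = x cosθ + y sinθ`, with linear
interpolation weights. Backprojection is implemented as the exact matrix
transpose of this operation, so `⟨Rx, y⟩ = ⟨x, Rᵀy⟩` holds to machine
precision — the test suite asserts it at 1e-6 relative. Filtered back
projection uses the standard band-limited discretization of the ramp filter
(`h[0] = 1/(4Δt²)`, `h[n odd] = −1/(πnΔt)²`, zeros at even lags), applied by
FFT with power-of-two zero padding, optionally Hann-apodized; the
backprojection is rescaled by `(π/n_angles)·Δt/h²` to undo the adjoint's
area weighting. On a noiseless 20 mm water-like disk the reconstruction
error inside the disk (2-voxel rim excluded) is ≈ 18 HU RMSE at 512 angles
and decreases monotonically with angle count.

**Noise model.** Reduced dose is simulated in the projection domain: per ray,
transmitted counts are drawn as `Poisson(d·I0·exp(−p))` and converted back
to a line integral with the counts clamped at one photon to stay finite in
photon-starved rays. Electronic noise, detector cross-talk, and vendor
weighting are not modelled; by the delta method the line-integral variance
is `exp(p)/(d·I0)`, which the empirical variance matches within 5 %. The
full-dose photon budget defaults to `I0 = 1e5` photons/ray; the high-dose
scan is itself simulated at full dose rather than noiselessly, mirroring
routine-dose acquisitions. Default dose fractions are 0.25 for abdomen and
head and 0.10 for chest.

**Phantoms.** Each scan is a short stack (8–32 slices by default) of analytic
ellipse compositions: a soft-tissue body (~35 HU), the exam type's organ —
liver (~55 HU), brain inside a bone rim (~40 HU inside ~700 HU), or two
lungs (~−700 HU) — a vertebral body for non-head scans, and at least one
low-contrast ellipsoidal lesion placed so that its integer bounding box lies
entirely inside the organ mask. Sizes, positions, and tissue values are
jittered uniformly per scan from a single integer seed via NumPy's
`SeedSequence` spawning, so a seed plus a configuration reproduces a
bit-identical dataset. Organs taper axially and are absent from the outer
~10 % of slices (with a minimum half-extent so that 1–3-slice stacks still
contain the organ), which gives the organ-presence slice filter something to
do.

## Metrics

All metrics operate on Hounsfield images per axial slice and are averaged
over slices, then scans, then retrain seeds. The data range is fixed
globally (default 2000 HU) rather than adapted per scan, because per-scan
ranges make cross-method comparison incoherent.

- **SSIM**: 11×11 truncated Gaussian window with σ = 1.5, K1 = 0.01,
  K2 = 0.03, population (not sample) covariances, and a half-window border
  crop — the original recipe. The implementation agrees with
  `skimage.metrics.structural_similarity` (Gaussian-weighted configuration)
  to better than 1e-6, and that library routine is used as an independent
  cross-check in the tests, never as the implementation.
- **PSNR**: `10·log10(L²/MSE)` in dB with MSE in HU²; identical images raise
  a dedicated error rather than returning a fake ceiling, and lesion-level
  summaries report +inf for exact agreement.
- **VIF**: pixel-domain, four scales. At each scale the images are blurred
  and decimated by 2; local moments use Gaussian windows of width 17, 9, 5,
  3 (σ = width/5); the score accumulates
  `log10(1 + g²σ_ref²/(σ_v² + σ_n²)) / log10(1 + σ_ref²/σ_n²)` with gain
  `g = cov/σ_ref²` and `σ_n² = 2` after rescaling HU to a 0–255 convention.
  A literal loop-based transcription of the same recipe serves as the test
  oracle (agreement to 1e-4).
- **Physical CT metrics**: CNR is `|μ_lesion − μ_background| / σ_background`
  over circular ROIs (the denominator convention is declared, since several
  coexist in the literature; note this makes CNR invariant under global HU
  rescaling), CT-number deviation is the absolute difference of ROI means
  against the high-dose scan, and line profiles are bilinear samplings along
  a segment.

## Radiomic feature similarity

Features are extracted inside the organ mask of the *high-dose* scan for
every algorithm, so mask differences never contaminate the comparison, and
shape features are excluded by construction (the mask is shared). The fixed
feature set has three families: 17 first-order statistics on raw HU values,
12 gray-level co-occurrence features and 14 gray-level run-length features
on values discretized at a fixed 25 HU bin width (bins anchored at the
masked minimum), with the 3-D texture matrices aggregated over the 13 unique
voxel directions. The exact feature list matters less than its fixedness:
the similarity is agnostic to the feature count.

Per scan, the feature matrix over algorithms (row 0 = high dose) is min–max
normalized per feature by subtracting the column maximum and dividing by the
column range, mapping every value into [−1, 0]; features constant across
algorithms are dropped (this avoids 0/0 while treating all methods equally).
The more conventional variant that subtracts the minimum (mapping to [0, 1])
is available behind a switch but is not the default. RFS is the cosine
similarity of each algorithm's normalized row against the high-dose row.
Consequences worth knowing: RFS is invariant to per-feature affine maps
applied across all algorithms and to feature permutations, and with only one
algorithm plus the high-dose row the normalized rows are complementary 0/−1
patterns, so RFS degenerates to 0 (or to an error when the rows are
identical — every feature is then constant). The metric is informative for
panels of three or more algorithms, which is how it is used here.

## Hyperparameter optimization

The SMBO loop draws `n_init = 5` configurations from the prior, then
repeatedly fits a Gaussian-process surrogate and evaluates the expected
improvement maximizer. Choices:

- Inputs are mapped to the unit cube, in log-space for log-uniform priors;
  integer parameters are optimized in continuous relaxation and rounded at
  evaluation time with clamping.
- Kernel: constant × Matérn 5/2 with per-dimension length scales, plus a
  white-noise term (jitter 1e-6, bounds to 1e-1) that also absorbs duplicate
  configurations with conflicting objectives; `normalize_y` on; one
  optimizer restart.
- EI uses the closed form with no exploration offset; the σ = 0 branch
  returns `max(μ − Ψ*, 0)`. The closed form is tested against a 10⁶-sample
  Monte-Carlo integral over a 27-point (μ, σ, Ψ*) grid.
- The acquisition is maximized over 512 seeded uniform candidates followed
  by three rounds of shrinking Gaussian local refinement — deterministic
  given (history, seed).
- Objective failures are recorded as NaN trials, excluded from the
  surrogate, and the loop continues.
- Defaults mirror the protocol: 50 iterations, validation-SSIM objective,
  10 retrain seeds at the tuned configuration. On the 1-D quadratic
  `−(λ−0.3)²` the optimizer recovers the optimum within 0.05 in at least
  9 of 10 seeds, and on a 2-D Branin-style surface its median best after 30
  evaluations beats random search at equal budget.

## Evaluation protocol and statistics

Splits are patient-level and per exam type: shuffle, then a contiguous
70/20/10 partition with largest-remainder rounding (50 patients → 35/10/5).
Training-slice sampling weights equalize exam types and patients:
`w = 1/(E·P_e·S_p)`. Test slices are filtered by organ presence: head keeps
slices with brain, chest keeps slices with lung, abdomen keeps slices
*without* lung. Normalization statistics (zero mean, unit variance per exam
type) are computed on the training split only and applied everywhere, to
avoid test leakage.

Mann–Whitney U is exact by enumeration of all `C(n+m, n)` group assignments
(mid-ranks for ties) when `n + m ≤ 14`, and tie-corrected normal
approximation with continuity correction otherwise; Wilcoxon signed-rank is
exact by sign enumeration for `n ≤ 12` with zero differences dropped.
Identical constant samples return p = 1 by convention. Significance marks
compare each method against the "previously published best": the method with
the best mean in that (exam type, metric) cell among strictly earlier
publication years, with the earliest methods compared against the low-dose
baseline; one-sided tests at α = 0.05 in each direction yield
better/worse/none. Ranking sums per-cell competition ranks (higher-better
for SSIM/PSNR/VIF/RFS/CNR, lower-better for RMSE/deviations) and
competition-ranks the sums: ties share a rank and the next rank is skipped.
Hard subsets take the `⌈q·n/100⌉` slices with the lowest method-averaged
SSIM per exam type, ties broken lexically by (scan id, slice index) — so
subsets are nested in q by construction.

## What the synthetic data does and does not show

The generator reproduces the *structure* of a paired-dose LDCT study —
three exam types, organ masks, lesion annotations, projection-domain dose
reduction, dose-dependent noise — but its images are far cleaner and
simpler than clinical scans: analytic ellipse anatomy, no scatter or beam
hardening, no anatomical texture, moderate noise at desk resolution (a
low-dose chest slice here scores SSIM ≈ 0.96 against its high-dose
reference, whereas clinical 10 %-dose chest data scores far lower). Passing
benchmarks on this data therefore demonstrates that the *protocol machinery*
— simulation physics, metrics, optimizer, statistics, ranking — is correct
and reproducible; it does not certify that any reference denoiser would
perform comparably on patient data. The plugin interface and the
DICOM/NIfTI readers are the intended path for real datasets.

## Problem sizes used by the test-bench

The library defaults (256² grid, 512 angles, 8–32 slices, 50 SMBO
iterations, 10 retrain seeds) are what a real study would use. The bundled
tests and the acceptance script run the same code paths at smaller sizes
chosen as the package's own desk-scale working set: 128² grids with 192
angles and 3–5 slices for end-to-end runs, 96² single-slice phantoms for the
100-seed noise-ordering Monte Carlo, and 10–15 SMBO iterations when tuning
the bilateral filter (its 2-D search space needs no more). The tiny CNN
trains for 450 Adam iterations on 32² patches (batch 16, learning rate
2e-3, residual architecture with a zero-initialized last layer so training
starts at the identity); this budget converges reliably across retrain
seeds at roughly 15 s per fit on one CPU.

## Known limitations

- 2-D parallel-beam physics only; no scatter/beam-hardening/TCM; the Poisson
  count model is a stand-in for vendor noise-insertion pipelines, not a
  reproduction of any of them.
- The radiomic feature list is fixed but package-specific; published
  91-feature panels from standard extraction tools will not match it
  feature-for-feature (RFS itself is robust to the panel choice).
- The printed-form RFS normalization maps to [−1, 0]; with very small
  algorithm panels the cosine geometry degenerates (see above).
- PSNR's data-range convention is declared (2000 HU) rather than inherited
  from any external definition; change `data_range` consistently across
  methods if another convention is needed.
- The reference denoisers are deliberately small; they exercise the
  benchmark, they are not competitive denoising research baselines.
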