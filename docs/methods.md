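# Methods

## Generative model

Each subject × ROI draws unit-variance Gaussian templates per emotion
*e* ∈ {happiness, anger, fear}: a face template **f**ₑ, a body template
**b**ₑ, and a person-only component **u**ₑ.  Between-emotion similarity
within a body type is induced by shared/idiosyncratic mixing,
fₑ = √ρ·g_f + √(1−ρ)·hₑ, so that corr(fₑ, fₑ′) ≈ ρ (default ρ = 0.3, a
moderate cross-emotion template overlap).  Face and body templates are
independent of each other and of **u**ₑ.  The whole-person template is

    p_e = γ (α_e f_e + (1 − α_e) b_e) + (1 − γ) u_e

* γ = 1 is the **part-based** scenario (the `part_based` scenario enum pins
  γ to 1); γ < 1 mixes in an **integrated**, person-specific signal.  γ is
  a free parameter because nothing constrains the magnitude of the
  person-only signal a priori; the shipped integrated cohort uses γ = 0.5.
* αₑ is the generating face weight.  The default cohort uses
  α = 0.65 for happiness and 0.50 for anger/fear, i.e. happy expressions
  weight the face more — the asymmetry the weight analysis is designed to
  detect.

Every run-level pattern is its template plus i.i.d. Gaussian noise of
standard deviation σ per voxel (no spatial autocorrelation: the templates
are the signal of interest and independent noise keeps all closed-form
oracle calculations exact).  Runs 1–3 carry all nine conditions
(3 body types × 3 emotions); the final run carries only the three
whole-person conditions, drawn from the same person templates with fresh
noise, so train (runs 1–3) and test (run 4) stay independent.

**Noise calibration.**  With unit-variance templates,
cov(person, synthetic mean) = γ/2,
var(person) = γ²(α² + (1−α)²) + (1−γ)², and the synthetic mean of a noisy
run has variance 1/2 + σ²/2, so the expected cross-run person–synthetic
Pearson correlation is available in closed form.
`noise_for_person_synthetic_r` inverts it numerically; the default
σ = 0.41 targets r ≈ 0.8 at α = 0.5, γ = 1 — a strongly part-based regime
in which similarity, weight, and decoding analyses all have clear signal.

## Block design and its arithmetic

A run is: an initial equilibration period of `n_discard · TR` (default
5 × 2 s; exactly the volumes discarded before analysis), then 18 blocks of
8 trials (2 s stimulus + 0.5 s ISI → a 20 s stimulation block) each
followed by a 2 s response window, with 10 s fixation between adjacent
blocks.  Total: 10 + 18·22 + 17·10 = 576 s = 288 acquired volumes at
TR 2 s, 283 retained — the only arrangement of these stated durations
consistent with both counts.  Condition order is balanced
pseudo-random (each of the 9 conditions twice per run; the person-only run
has 6 blocks per emotion).

Voxel time courses are condition regressors (block boxcars convolved with
the canonical double-gamma response: peak 6 s, undershoot 16 s, ratio 1/6,
unit peak, fine grid dt = 0.1 s) weighted by that run's pattern values,
plus a nuisance contribution (six motion-like random walks and two slow
tissue-average signals, per-voxel loadings scaled by `nuisance_scale`,
default 0.3), a constant baseline (100), and white noise (default SD 0.5;
an AR(1) switch exists for the time-series generator only).  Because the
generator and the estimator share the same regressor construction,
ordinary least squares recovers the generating amplitudes to machine
precision in the noiseless case — the identifiability contract the tests
assert at 1e−8.

## The two pattern-recovery procedures

1. **GLM betas** (similarity and weight analyses).  Per run, the design
   matrix holds one convolved boxcar per condition, the 8 nuisance
   regressors and their temporal derivatives, and an intercept (26 columns
   for a 9-condition run).  Zero columns are dropped with a warning;
   genuine rank deficiency raises with the offending labels.  Estimation is
   OLS without prewhitening — at the noise structure simulated here
   (white, optional AR(1)) GLS would change nothing material, and OLS keeps
   the projection-invariance property exact.
2. **Volume extraction** (classification).  A volume acquired at time *t*
   is labelled with a condition when *t − shift* falls inside one of its
   stimulation blocks (half-open intervals).  The hemodynamic shift
   defaults to **2 s (1 TR)**: with the 576 s run above, any shift larger
   than 2 s pushes the last block's shifted window past the run end and
   truncates it to 19 volumes, whereas a 1-TR shift yields exactly 20
   volumes per condition per run — the count the design promises.  The
   shift is exposed (`--shift`); truncating shifts warn, impossible shifts
   raise.  Response-window and fixation volumes are assigned to no
   condition, so extraction is a partial partition of the timeline.

## Statistics

* **Fisher z**: atanh with |r| clipped to 1 − 1e−7, keeping z finite at
  exact collinearity while preserving strict monotonicity.
* **Cross-run correlations**: for distinct categories both directed
  comparisons of each of the 3 run pairs are averaged (6 z-values; 3 for
  same-category reliability).  Synthetic means are built within-run before
  correlating, preserving run independence.  Zero-variance patterns skip
  their pair with a warning.
* **Repeated-measures ANOVA**: closed-form two-way fully-within
  sums-of-squares (each main effect tested against its factor × subject
  interaction; the interaction against the three-way residual), no
  sphericity correction.  Implemented in numpy so calibration studies can
  run thousands of replicates; validated against `pingouin.rm_anova` on
  random instances in the test suite.  Zero error variance is reported as
  an explicit degenerate result (F = NaN), never silently.
* **Weight grid**: closed grid 0.00–1.00 step 0.01, no continuous
  refinement.  Ties (up to last-bit rounding, tolerance 1e−9 relative) are
  broken to the smallest α and counted; an analytically constant curve
  (face = body) reports a 101-way tie.  Correlation is maximised; z is
  stored since atanh is monotone.  Group statistics run on body weights
  β̂ = 1 − α̂; paired follow-ups are reported pooled (emotion comparisons
  pool ROIs, ROI comparisons pool emotions) and the unpooled tables are
  exported alongside.
* **Classification**: z-scoring per voxel per run over that run's pooled
  stimulus volumes (zero-variance voxels set to 0 with a warning); one-way
  ANOVA feature selection across all nine conditions of the training runs
  only (p < 0.05; the leakage guard is asserted in tests); linear SVC,
  C = 1, one-vs-one; mean/weighted-mean training exemplars pair the k-th
  face and body volumes within run and emotion.  Run-4 person volumes are
  classified volume-wise by default with a block-wise averaging option.
  Chance is the analytic 1/3; a permutation null (training labels shuffled)
  is available.  Group tests are one-sample t vs 1/3 with
  Benjamini–Hochberg FDR across all ROI × training-type cells; an
  all-identical accuracy cell (possible at very small n on saturated
  synthetic data) is flagged degenerate and assigned a conservative raw
  p = 1 so the family size is preserved.
* **Stimulus statistics**: the movement threshold (10) applies to the
  inter-frame *difference* image — the alternative reading (thresholding
  raw luminance) is available via `threshold_on="luminance"` — and
  frame pairs with no supra-threshold pixel count as zero movement.
  Contrast uses the population (not sample) SD.  Clips of differing length
  compare via per-clip scalars.

## Calibration studies and problem sizes

The suites verify, at sizes chosen to make each check decisive on one CPU
in a few minutes: weight recovery within ±0.05 of five generating α values
(20 subjects, 600 voxels, σ tuned to r ≈ 0.8); one-sample-test rejection
rates over 200 replicates (α = 0.35 rejected and α = 0.5 retained in
≥ 90 %); grid-search agreement with exhaustive brute force on 100 random
instances; part-based vs integrated (γ = 0.5) separation in ≥ 95 of 100
paired seeds; type-I calibration of the repeated-measures ANOVAs and group
t-tests at 5 % ± 1.5 % over 1000–2000 null replicates; and ANOVA feature
selection retaining ≈ 5 % of null voxels (binomial 99 % interval on 2000
voxels).

The **permutation-null chance check** is calibrated on signal-free data
(condition amplitudes zeroed, nuisance off).  With visible template signal
the permutation distribution remains centred on chance by symmetry, but all
test volumes of an emotion share one template realisation, so accuracies
cluster at the fixed-point fractions {0, 1/3, 2/3, 1} of the label map and
the Monte-Carlo mean of 100 permutations is too dispersed to certify a ±3
percentage-point band.  Signal-free calibration is the standard way to
verify a permutation null's centring; the trimodal behaviour on strong
signal is a property of block-structured test sets, not of the classifier.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: per-condition
multi-voxel templates with controlled part-based/integrated mixing,
run-level noise, cross-emotion template similarity, block-design
hemodynamics with nuisance confounds, and the exact run/volume bookkeeping.
It does **not** emulate spatial autocorrelation or voxel-size effects,
subject-specific HRF variability, motion artifacts or their interaction
with the design, physiological noise spectra, or realistic face/body video
content (stimulus clips are random fields with programmable motion).
Passing tests therefore certify the *analysis machinery* — recovery,
calibration, and scenario discrimination under the stated assumptions —
not performance on real scanner data.

## Known limitations

* OLS without prewhitening mildly mis-states GLM standard errors under
  AR(1) noise; only point estimates (betas) feed the downstream analyses,
  so the group statistics are unaffected.
* The 0.01 grid bounds weight precision at ±0.005; recovery claims are
  made at the ±0.05 level.
* With very few subjects the α grid can make every subject's optimum
  identical; the group t-test then reports an explicit degenerate result.
* The RSM diagonal holds cross-run same-category reliability; it is
  exported but no hypothesis test uses it.
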