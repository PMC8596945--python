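# Methods

## Model

`escimap` treats a group-level fMRI analysis as a GLM `Y = Xb + e` per
voxel, with a contrast *c* tested by `t = c′b / sqrt(s² c′(X′X)⁻ c)` on
`DoF = N − rank(X)` error degrees of freedom.  Everything the package
computes derives from two design quantities:

* the **contrast variance scale** `sqrt(c′(X′X)⁻ c)`, computed with a
  pseudoinverse (tolerance-based rank determination, so rank-deficient
  designs such as two group indicators plus an intercept are handled);
  a contrast outside the row space of X is rejected as non-estimable;
* the **degrees of freedom** `N − rank(X)`; covariate columns reduce the
  DoF by their rank contribution and, when correlated with the contrast
  columns, are reflected in the scale.

The uncorrected standardized effect is `d_p = t · scale`, reducing to the
textbook `t·sqrt(1/n1+1/n2)` (two-sample) and `t·sqrt(1/n)` (one-sample)
forms.  The point estimate is bias-corrected to Hedges'
`g = d_p · J(DoF)` with `J = 1 − 3/(4·DoF − 1)`; the exact gamma-function
form of J is available behind `exact_j=True`, but the algebraic
approximation is the default because it is the form in universal use and
the difference is < 2·10⁻³ for DoF ≥ 5.

### Exact confidence intervals

The observed *t* estimates the noncentrality parameter Δ of a noncentral
t-distribution with the analysis DoF.  The two-sided (1−α) CI limits for Δ
solve `F(t; DoF, Δ_l) = 1 − α/2` and `F(t; DoF, Δ_u) = α/2`, and the
effect-size CI is `(Δ_l · scale, Δ_u · scale)`.  Two deliberate
consequences:

* the CI limits are **not** multiplied by J — only the point estimate is
  biased; correcting the limits would break the exact significance
  correspondence;
* the lower bound of the two-sided (1−2α) interval is positive **iff** the
  one-sided p-value is below α.  This is the mathematically exact pairing;
  a "99.9% CI lower bound above zero" call is therefore slightly more
  conservative than one-sided p < .001 (which pairs exactly with the
  99.8% interval).  The test suite asserts the exact pairing.

An approximate normal-theory interval based on
`se_g = sqrt((n1+n2)/(n1·n2) + g²/(2(n1+n2−2)))` is provided
(`se_g_approx`) but clearly flagged as the approximate alternative; no
other computation uses it.

### Numerical choices

* Scalar root-finding: Brent's method on an expanding bracket
  `[t − k·sqrt(DoF), t + k·sqrt(DoF)]` with k doubled until the target is
  straddled; acceptance tolerance 10⁻⁶ on the CDF residual (achieved
  residuals are ~10⁻¹²).
* Map-level root-finding: per-voxel bracket expansion followed by 48
  vectorized bisection steps on the noncentral-t CDF — identical defining
  equations, throughput-oriented; the suite checks scalar/map agreement to
  10⁻⁶ and both against an independent brute-force bisection oracle to
  4 decimals.
* scipy's noncentral-t CDF returns NaN deep in the lower tail; the package
  falls back on the reflection identity `F(t; ν, δ) = SF(−t; ν, −δ)` and,
  as a last resort, clamps to the limiting 0/1 value.
* Non-finite t values (out-of-mask or degenerate voxels) propagate as NaN
  through every map operation and never become finite; the scalar API
  raises instead.

## Inference procedures

All three procedures consume the fitted g/CI bundle; the key boundary
conventions are fixed package-wide:

* **Undecidability**: voxel is undecidable iff `ci_upper ≥ reference`
  (inclusive — "including or exceeding" counts against inferiority).
  Symmetrically, an inferiority call requires strictly `ci_upper <
  bound`, and equivalence requires strict containment within the bounds.
  The cluster that supplied the reference is excluded from the output by
  default (it is already decided).  The reference is an order statistic of
  an actual cluster voxel, nearest-rank (`ceil(p·n)`; median = lower of
  the two middle ranks for even n), so the reported reference always
  exists at a reported voxel index.
* **Replication**: replicated iff the reference g falls into the
  replication CI read as a **closed** interval.  Only voxels with
  reference g > 0 are evaluated (one contrast direction); output encodes
  {replicated, not replicated, not evaluated} as {1, 0, NaN}.  The
  confidence level is an explicit parameter (default 0.90).  Evaluation is
  brain-wide wherever the reference g > 0; stricter masking is left to the
  caller.
* **Lateralization**: the cluster's percentile reference (default 75th) is
  compared against CI upper bounds inside the cluster mask mirrored across
  the grid midline of the left-right voxel axis.  The axis is inferred
  from the affine's dominant world-x direction and can be overridden
  (`mirror_axis`), since real acquisitions are rarely perfectly
  midline-symmetric.  Clusters straddling or touching the midline are
  rejected; an empty result supports lateralization.

No multiple-comparison widening of CIs is applied; uncorrected maps are
the lower bound of the undecidable regions (widening the CI can only
enlarge them — a monotonicity the tests assert).  A Bonferroni-style
confidence adjustment can be emulated by passing a higher confidence.

## The synthetic-data generator

The simulator emulates a two-group voxel-wise study on one slice:

* **Signal**: circular regions with hard edges in which group B's mean is
  shifted by `d · noise_sd`; the canonical three-effect layout places
  d = 0.28, 0.50, 0.50 on the middle row at 1/4, 1/2, 3/4 of the slice
  width (default grid 400×400), radius 1/24 of the width.
* **Noise**: per-subject white Gaussian fields, smoothed with an isotropic
  Gaussian kernel using circular boundaries, then rescaled by the exact
  kernel norm so the marginal per-voxel SD equals `noise_sd` (default 1.0)
  — hence the realized standardized effect at an effect voxel equals the
  declared d in expectation, independent of smoothing or grid size.
* **Smoothness**: default FWHM is 5% of the slice width.  Fixing
  smoothness as a fraction of the field of view (rather than a voxel
  count) mirrors fMRI practice, where the kernel is chosen in millimetres
  (~8–10 mm on a ~200 mm slice), and makes the generator's spatial
  statistics invariant under grid re-scaling.  This choice also puts the
  small-sample regime in the scientifically interesting zone: the peak
  effect of the detected cluster is then only moderately inflated, so at
  n = 50 per group the d = 0.5 effect that misses the p < .001 threshold
  typically remains statistically indistinguishable from the detected
  peak — the motivating "undecidable region" phenomenon, which the suite
  checks as a seeded-majority property.  With much finer smoothness the
  detected peak is so inflated by selection that undecidable regions
  almost never appear.
* **Randomness**: one integer seed governs a study; per-subject noise
  streams are spawned deterministically from it, so regeneration is
  bit-identical.

### What the generator does *not* emulate

Temporal autocorrelation, physiological noise, field inhomogeneity,
between-subject variance heterogeneity, non-Gaussian tails, and realistic
anatomy (the "brain" is a homogeneous slice).  Passing tests therefore
validate the statistical machinery — conversion, CIs, coverage, the
inference procedures' logic — not robustness to real fMRI artifacts.
Significance thresholding here is uncorrected and voxel-wise; FWE-corrected
cluster masks for the real-data procedures are user inputs, and the
simulator's "detected cluster" is simply the uncorrected p < .001 mask.

## Problem sizes used in the automated checks

The statistical guarantees are grid-size-free (see above), so the
validation suite and the reproduction script run the slice experiment at
desk scales: 96×96 (suite) and 128×128 (reproduction script) for the
50-seed recovery and correspondence checks, with one full-size 400×400 run
for the headline large-sample quantities.  Coverage checks use 10,000
scalar two-sample replicates (n = 50 per group, δ = 0.5).

## Known limitations

* Designs must be supplied as delimited text; native SPM `.mat` files are
  not parsed (export the design matrix and contrast first).
* Only the d-family effect size for t-contrasts is covered (no F-tests,
  no correlation-family effect sizes).
* Bootstrap CIs are not implemented; the exact noncentral-t route is
  always used.
* The mirroring used by the lateralization test assumes a grid that is
  (approximately) symmetric about its midline; spatially normalize first.
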