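# Methods

This note documents the model, the numerical choices and the limitations
of the `emospace` pipeline, in the package's own terms.

## Rating model and units

The instrument is a visual-analogue judgment: one mark on a 10 cm line
per (participant, emotion, aspect), read in millimetres from the left
end, so every rating lives on a continuous 0–100 scale (left pole = low:
unpleasant / calm / uncontrolled / harmful).  Ratings are stored as
decimal millimetres — the instrument is continuous even if transcription
is to 1 mm — and missing cells are permitted (NaN), excluded cell-wise
from summaries and pairwise from correlations.  Cell summaries report the
arithmetic mean and the sample SD (n−1 denominator, the common reporting
convention in this literature); constant cells return the exact value so
that zero-variance synthetic pipelines reproduce downstream matrices
bit-for-bit.

## Proximities

* **Profile distances.**  Emotions are placed in the theoretical 4-aspect
  space at their mean rating vectors; dissimilarity is the Euclidean
  distance, with range [0, 100·√4] = [0, 200].  The four-aspect form is
  enforced (the construction is about those four qualities); a
  generalised √Σ over k aspects exists behind an explicit flag.
* **Correlation-derived proximities.**  For each aspect, the emotion ×
  emotion Spearman correlation across participants (average ranks for
  ties; pairwise-complete observations; a zero-variance emotion is an
  error naming the emotion) is mapped to a dissimilarity by the exact
  linear rule d = 1 − r, which sends r = 1/0/−1 to 0/1/2.  No rescaling
  to [0, 1] is applied.  One matrix per aspect, identical label order,
  forms the multi-source MDS input.
* **Aspect independence.**  All six aspect pairs are correlated and
  Bonferroni-corrected (adjusted p = min(1, 6p)).  The unit of analysis
  is genuinely ambiguous for this design, so both are offered:
  `pooled_observations` (flattened participant × emotion vectors) and
  `emotion_means` (16 mean profiles).  Neither is privileged.  Note that
  pooled-unit correlations pick up *between-emotion* mean structure even
  when every cell is drawn independently, so a significant pooled result
  on synthetic data is not a generator defect.

## Multi-source MDS

The engine (`MultiSourceMDS`) fits the identity model: one common
configuration X for all K sources, no source weights, metric (ratio)
treatment of the proximities.  The loss is normalized raw stress

σ(X) = Σₖ Σ_{i<j} wᵢⱼₖ (δᵢⱼₖ − dᵢⱼ(X))² / Σₖ Σ_{i<j} wᵢⱼₖ δᵢⱼₖ² ,

with unit weights by default and weight 0 for missing entries; total
fit = 1 − σ.  Because the per-pair quadratic terms add across sources,
the pooled problem reduces exactly to a weighted single-matrix SMACOF on
the weighted mean source (pair weight Σₖ wᵢⱼₖ), and each iteration
applies the Guttman transform X⁺ = V⁺ B(X) X.  Majorization guarantees a
non-increasing stress sequence, asserted on every run.

Numerical choices:

* **Initialisation.**  Default is classical (Torgerson) scaling of the
  mean source — double-centering −½ J D² J, eigendecomposition, top-p
  axes with negative eigenvalues clipped.  A `simplex` start (centered
  regular-simplex vertices, exact for p = n−1, principal-axis projection
  below that) and a seeded `random` start are provided; `n_restarts`
  seeded random restarts keep the best-stress solution as a local-minimum
  guard.
* **Convergence.**  Stop when the per-iteration stress improvement falls
  below `tol` (default 1e-4, the conventional default for this family of
  programs) or at `max_iter` (1000).  Zero distances in the Guttman
  transform use the standard 0-ratio convention.
* **Identification.**  Solutions are defined only up to translation,
  rotation and reflection.  Fitted configurations are mean-centered but
  *not* rotated to principal axes; all cross-configuration comparisons go
  through distance matrices or Procrustes alignment.
* **Scree and selection.**  One independent fit per dimensionality
  (optionally warm-started from the previous solution padded with a zero
  column, which makes fit non-decreasing in p); the chosen p is the
  smallest whose successor adds less than `gain_threshold` (default
  0.01) total fit, falling back to the largest p with a warning.
* **Qualitative stress labels.**  The conventional rule-of-thumb bins
  are half-open intervals anchored at 0 (perfect), 0.025 (excellent),
  0.05 (good), 0.1 (fair), 0.2 (poor), with larger values labelled
  unacceptable.

## Configuration analysis

* **Matrix correlation** uses the strict lower triangle (120 pairs for
  16 objects).  The naive p-value treats those pairs as independent —
  they are not, since entries share objects — so a Mantel-style
  permutation p (simultaneous row/column permutation of one matrix,
  one-sided greater, observed ordering counted in the numerator) is
  available and recommended whenever inference matters.
* **Frontiers** are per-dimension coordinate extremes; runners-up within
  a margin (default 0.05, chosen so jointly-extreme groups of emotions
  are reported together rather than hiding near-ties) are listed, exact
  ties broken by label order and flagged.
* **Central area** is not defined quantitatively in the source
  literature, so it is a parameter: the origin-centered ball with radius
  a fraction (default 0.25) of the largest point norm.  The check
  requires a centered configuration; coordinates printed at 3 decimals
  are accepted as centered (tolerance 1e-2) while engine output is held
  to 1e-9.
* **Procrustes alignment** implements the closed form (translation +
  orthogonal transform via SVD, optional uniform scaling); disparity is
  the minimised sum of squares normalised by the centered sum of squares
  of the target, in [0, 1] with scaling.

## Reference tables and known inconsistencies

The packaged reference data (16 emotions × 4 aspects, 187 raters) are
published summary tables, shipped verbatim:

* The published 4D profile-distance entries involving **envy** are not
  reproducible from the published means (errors up to ≈ 22 on the 0–200
  scale, e.g. love–envy prints 114.2 but recomputes to ≈ 97.1), while
  all 105 other pairs reproduce within 0.15.  Either the envy mean row
  or the envy distance column contains a transcription error; the
  package reproduces from the means and does not guess a correction.
* Three published SDs (envy arousal 49.3, contempt arousal 43.8,
  happiness control 62.2) are implausibly large relative to neighbours —
  49.3 is essentially the theoretical SD bound of *any* [0, 100]
  variable with that mean, and 62.2 exceeds it.  They are accepted
  verbatim as generator targets, with the realised-SD shrinkage below.
* The published 3D coordinates are mean-centered only to their printed
  3-decimal precision; centering checks account for this.
* The published solution's own total fit (0.96), its stress trajectory
  and its exact coordinates derive from the unreleased per-participant
  data and are **not** reproduced or asserted; the engine's correctness
  is instead established by property tests (monotone stress, equivalence
  with a brute-force optimizer on small instances, recovery of planted
  configurations) and the published coordinates are used only as a
  downstream fixture.

## Synthetic data: what it emulates and what it does not

`simulate_ratings` draws each cell from a normal distribution truncated
to [0, 100] by exact inverse-CDF sampling (no boundary point masses, the
same distribution a rejection sampler would produce).  The underlying
location is calibrated per cell (root-finding on the truncated mean) so
the realised cell *means* are unbiased for the targets; realised *SDs*
are shrunk by truncation for boundary-near cells, and far below target
for the three anomalous published SDs, which no truncated normal on
[0, 100] can realise (the family's SD supremum on that interval is
≈ 28.9).  Infeasible cells — boundary means with positive SD, or targets
requiring a location shift beyond 3.7 SD (acceptance < 1e-4 for the
equivalent rejection sampler) — raise a feasibility error rather than
silently distorting.  Defaults are 187 participants and the published
cell moments; every stochastic draw requires a seed and is exactly
reproducible from it.

By default cells are independent across emotions and participants.  That
reproduces the marginal moments but **no** inter-emotion correlation
structure, so the correlation-derived sources from default synthetic
data carry sampling noise only: the resulting MDS fit (≈ 0.94 at p = 3
for 187 raters) reflects how much of pure noise a 3D configuration can
absorb, and the synthetic 4D-vs-3D matrix correlation is near zero, not
the ≈ 0.76 of the real data.  Passing tests on default synthetic data
therefore validate the *mechanics* of the pipeline, not claims about
real raters.  For structure-sensitive checks, `PlantedStructure` plants
a latent configuration: target inter-emotion correlations are
r = 1 − distance/max distance (clamped; the inverse of the d = 1 − r
proximity transform, so the planted geometry survives the pipeline),
realised through a shared-factor multivariate-normal construction
(nearest-PSD projection by eigenvalue clipping), with whole-participant
redraws keeping rows inside [0, 100].  `simulate_sources` bypasses
ratings entirely and perturbs a known configuration's distance matrix
with multiplicative N(0, noise_sd²) noise per pair and source (clipped
at 0, symmetric, zero diagonal) — the primary fixture for recovery
studies.

No anchoring, acquiescence or other psychometric response biases are
modelled, and the true participant-level covariance of the original
study is unknown; synthetic defaults are labelled as such and are not
estimates of the study sample.

## Problem sizes used in tests and the acceptance script

Table reproductions run on the full 16-emotion tables.  Engine
guarantees use: planted 16 × 3 configurations with 4 sources at 5%
multiplicative distance noise over 20 seeds (recovery disparity
< 0.05); brute-force optimizer comparisons on 4–6-object 2D instances
with 50 L-BFGS-B multistarts (agreement within 1e-4 stress); zero-noise
recovery and scree saturation at the planted dimensionality; synthetic
end-to-end replications at the full 187 × 16 × 4 size.  A null
calibration of the aspect-independence test uses 1000 replicates of 150
independent observations per aspect.

## Known limitations

* Metric MDS only: no ordinal (non-metric) transformation stage, no
  INDSCAL-style weighted individual-difference models.
* The identity model cannot express systematic disagreement between
  sources; sources that genuinely demand different geometries simply
  raise stress.
* Frontier and central-area readings inherit the arbitrariness of any
  single MDS solution's axes; only the distance structure is
  rotation-invariant.
* The generator's independence default understates the real data's
  shared structure (see above); planted-structure specs are a model of
  convenience, not of rater psychology.
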