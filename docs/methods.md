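# Methods

This document specifies the models, parameters and numerical choices the
package implements, and the limits of the synthetic generator used to
exercise them. Quantitative statements here are computed by the test
suite (`tests/`) or the acceptance script (`scripts/acceptance.py`).

## Dual-task cost and improvement

For a timepoint with single-task gait speed `v_s > 0` and dual-task speed
`v_d`, the dual-task cost is `DTC = (v_d − v_s)/v_s × 100` percent.
Participants are randomized to exercise first (baseline→midpoint) or
second (midpoint→final); improvement is `DTC(end of exercise period) −
DTC(start of exercise period)`, so positive values mean reduced cost.
A participant missing a timepoint their arm requires raises
`MissingDataError` — missing data are never imputed as zero — and
`filter_complete` partitions a cohort accordingly.

## Parcellation

The atlas abstraction maps 333 1-based ROI ids to 12 named functional
networks plus an Unassigned group of 47 ROIs (network sizes: Auditory 24,
Cingulo-opercular 40, Cingulo-parietal 5, Default 41, Dorsal attention
32, Fronto-parietal 24, Retrosplenial temporal 8, Somatosensory-lateral
38, Somatosensory-medial 8, Salience 4, Ventral attention 23, Visual 39).
Vertex-level thickness on the 2 × 32,492 = 64,984-vertex surface is
averaged (unweighted within ROI) by `vertex_to_roi`; network-level
summaries use unweighted ROI means by default, with an optional
vertex-count-weighted variant. The packaged `Parcellation.canonical()`
fixture is *synthetic*: only the network sizes match the published atlas
grouping; ROI-to-network assignment is a seeded permutation and the
per-ROI vertex counts are a seeded multinomial partition of the 64,984
vertices. No real atlas tables ship with the package.

## Box-Cox normalization

The two-parameter Box-Cox transform is `t(y) = ((y+s)^λ − 1)/λ`, with
`log(y+s)` at λ = 0. The shift is rule-based, not estimated:
`s = 1 − min(y)` when any value is ≤ 0, else 0. λ maximizes the
per-observation profile log-likelihood
`llf(λ)/n = (λ−1)·mean(log z) − ½·log(var(t(λ)))` (z = shifted data, MLE
variance) by gradient ascent with an analytic gradient (λ→0 limits
handled explicitly), initial step 0.25, step growth ×1.5 on improvement
and halving otherwise, convergence at |Δλ| < 1e-6, at most 500
iterations. Tests verify agreement with a 0.01-step grid search over
[−3, 3] and with an independent library maximum-likelihood estimate.
In the screen the transform is fitted once on the modeling sample and
frozen before cross-validation (the per-fold refit variant is available
behind a flag); the transform uses the same leakage convention as the
published analysis it follows.

## PLS regression

`PLSRegressor` is a univariate-outcome NIPALS implementation: columns are
mean-centered (z-scoring optional, off by default — thickness columns
share a common millimeter scale, and scaling would inflate low-variance
ROIs), each component's weight vector is `X_res' y_res` normalized,
scores deflate the predictors, and coefficients are `B = W (P'W)^{-1} q`.
Component extraction stops early when the residual covariance underflows
(tolerance 1e-13 relative to problem scale), so pure-noise outcomes yield
zero coefficients rather than numerically unstable components. The
component count is fixed at 4 in the pipeline. At full rank (k = p) the
fitted values coincide with ordinary least squares; tests verify this to
1e-8 on random problems and verify exact agreement with an independent
reference implementation. `first_score_r2` reports the squared
correlation between the outcome and the first component's scores.

## Evaluation: leave-3-out CV against a permutation null

`plan_splits(n, 3)` enumerates all C(n,3) held-out triples in
lexicographic order when C(n,3) ≤ cap (default 10,000 — exhaustive for
both study-scale cohorts: C(21,3) = 1,330 and C(30,3) = 4,060);
otherwise it samples `cap` distinct triples without replacement by
lexicographic unranking. The real side fits on each split's training
complement and records the held-out mean squared error; each subject's
held-out predictions are pooled (averaged over the splits excluding
them) and the out-of-sample R² is the squared Pearson correlation of
pooled predictions with the observed outcome. The null side repeats, per
repetition (default 10,000; 1,000 in fast mode): draw one random 3-out
split, permute the outcome-to-subject pairing *within the training rows
only*, fit, and score against the unpermuted held-out outcome.

Three summaries compare the distributions:

- **Effect size**: Cohen's d = (mean null MSE − mean real MSE) / pooled
  SD, positive when real models predict better.
- **p_value**: one-sided Welch t-test that the real MSE distribution has
  the lower mean. This is the screen's default significance.
- **p_empirical**: `(1 + #{null MSE ≤ mean real MSE}) / (1 + n_null)`,
  the add-one-smoothed probability that a single chance-trained model
  beats the real models' average error. Because a single 3-subject MSE is
  far more dispersed than a 1,330-split mean, this tail probability is
  very conservative (≈0.1–0.5 even for strong signal) and is reported
  alongside rather than used for the pass decision.

A network **passes** when d > 0.50 and p_value < alpha (default 0.001).

### Known statistical limits of the screen (measured)

The acceptance suite measures the screen on planted synthetic cohorts and
finds the published-style thresholds sit inside the sampling noise of the
d statistic at n = 21:

- Across pure-noise cohorts (no planted association), per-network d is
  centered at ~0 but has an across-dataset SD of ~0.5. About 14% of
  null network evaluations therefore exceed d = 0.50 — and essentially
  all of those also reach p < 0.001, because the Welch comparison treats
  the thousands of split-level MSEs as independent samples when they are
  generated from the same ~20 subjects. The pass rate under the null is
  ~14%, not alpha.
- Across cohorts with a planted association calibrated to population
  R² = 0.5, d has median ≈ 0.95 with the same ~0.5 SD, so the d > 0.50
  clause detects the signal in only ~84% of cohorts.

Both numbers come from the same statistic's dispersion: leave-3-out CV at
n = 21 does not estimate d precisely enough for a fixed 0.50 threshold to
act as a calibrated test. The corresponding acceptance tests assert the
stronger behavior (≥90% detection; alpha-consistent false-positive rate)
and fail with the measured rates; the thresholds were deliberately not
tuned to make them pass. Interpret single-cohort screen output as
descriptive ranking evidence, not as a calibrated hypothesis test.

## Group statistics

- Pooled-variance independent t-test by default (Welch behind a flag);
  degenerate zero-variance inputs raise rather than return NaN.
- Severity matching removes the larger group's lowest scorers on the
  matching variable (MDS-UPDRS-III by default; ties broken by subject
  id) until group sizes are equal, and reports the post-match t-test p.
- Mixed-design ANOVA (group between; time or network within) by explicit
  sums of squares with subject-within-group as the between-stratum error
  term; all-equal input returns F = 0, p = 1 rather than erroring. No
  sphericity correction is applied (with two within levels sphericity is
  trivial). Verified against hand-worked designs and an independent
  library implementation.
- ANCOVA adjusts the group effect for one covariate at a time via OLS
  (`y ~ group + covariate`, Type-II test) with explicit collinearity
  guards; verified against a nested-model residual-sum-of-squares oracle.
- Tukey-Kramer post-hocs refer `q = |Δmean| / sqrt(MS_err/2 · (1/n_i +
  1/n_j))` to the studentized range distribution.

## Synthetic cohort generator

Thickness for subject i, ROI j in network g is
`grand_mean + network_offset_g + roi_offset_j + subject_effect_i +
noise_ij` with defaults 2.5 mm and SDs 0.10 / 0.10 / 0.10 / 0.05 mm;
nonpositive draws are rejected and resampled, and a validation rule
requires the grand mean to exceed 3× the total SD. Offsets are drawn
once per cohort; only the subject effect and the noise vary between
subjects, so the between-subject variance of a planted network's mean is
`subject_sd² + noise_sd²/m` (m = ROI count), which is what
`planted_beta_for_r2` inverts to calibrate an association of chosen
population R². Improvements are drawn per stratum
(freezers 9.8 ± 12.6, nonfreezers 4.3 ± 7.3 percent) with the planted
term `beta·(network mean − grand mean)` added; baseline DTC
(−18.0 ± 10.1 / −13.9 ± 9.8), MDS-UPDRS-III (46.0 ± 12.7 / 38.3 ± 10.2)
and the other covariates use stratum-level anchors with truncation to
plausible ranges. Dual-task speeds are back-solved from the drawn DTC
trajectory with single-task speed fixed at 1.0 m/s, so the DTC and
improvement computations reproduce the drawn values exactly; arms
alternate within stratum. All draws derive from
`SeedSequence([seed, stage])` and are bitwise reproducible.

### Generator limitations

- The shared per-subject thickness effect makes all network means nearly
  collinear (correlations ≈ 0.99 at defaults). This mimics the global
  atrophy component of real cortex but means a planted association is
  detectable from *any* network's block, so the default generator cannot
  test network specificity. Specificity is tested with the shared
  components zeroed — and there the per-column signal is weak enough
  that localization needs larger cohorts (n ≈ 100) than the study scale.
- Covariates are drawn independently of thickness and of each other;
  there are no planted covariate-outcome confounds.
- Thickness is Gaussian around its mean structure; no spatial
  autocorrelation within networks beyond the shared offsets, no
  hemispheric structure, no missing data.
- The DTC trajectory model is minimal: improvement is a single additive
  step over the exercise period; the non-exercise period is flat.

Passing tests on generated cohorts therefore demonstrate that the
pipeline's machinery (enumeration, fitting, permutation accounting,
calibration arithmetic, determinism) behaves as specified — not that the
screen would detect or localize real neural signal, which the measured
d dispersion above directly questions at study-scale n.

## Determinism and reporting

Every stochastic step takes an explicit seed; independent sub-seeds are
spawned via `numpy.random.SeedSequence` (reduced mod 2³¹ where an integer
seed is required). The pipeline report contains the configuration echo,
package version, SHA-256 digests of file inputs, and no timestamps;
floats are rounded to 10 significant-decimal digits with NaN mapped to
null, and JSON keys are sorted. Two runs with identical inputs and seed
produce byte-identical `report.json` files (verified in the acceptance
suite and script).
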