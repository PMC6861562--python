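# Methods

## Generative model of the synthetic cohorts

Each subject has a chronological age Ω drawn uniformly on
[`age_low`, `age_high`] (default 47–94 years). Uniform sampling is a
modeling choice — it is the simplest distribution with a closed-form
variance ((94 − 47)²/12 ≈ 184 y²), which every calibration below relies
on. A clinical group g carries an additive brain-age acceleration
`group_offsets[g]` (defaults CN 0, MCI +2.0, AD +4.1 years), so the latent
brain age is Ω + offset.

Two data paths feed the downstream machinery:

1. **Feature path** (`generate_cohort`): feature_j = intercept_j +
   loading_j · (Ω + offset) + N(0, sd_j). The regression backends then
   *produce* attenuation: for a single feature with loading λ and noise sd
   σ, the in-sample attenuation factor is k = λ²Var(Ω)/(λ²Var(Ω) + σ²);
   with p independent features the effective noise variance divides by p.
   The defaults (10 features, unit loadings, σ = 65 year-equivalents) give
   k = 184.1/(184.1 + 65²/10) ≈ 0.30, i.e. a delta-on-age slope near −0.7 —
   the bias level the package is built to correct. Note that on this path
   the group acceleration sits on the *latent* axis, so the regressor
   attenuates disease effects exactly as it attenuates the age signal;
   recovered group contrasts are correspondingly shrunk. That is a real
   property of dilution, not an artifact.
2. **Prediction simulator** (`simulate_predictions`): predicted =
   pivot + a·(Ω − pivot) + offset + N(0, sd). This bypasses the regressor
   so corrections can be tested against an exactly known bias line: the
   population delta-on-age line has slope a − 1 and intercept
   (1 − a)·pivot, and the delta–age correlation is
   (a − 1)·sd(Ω) / sqrt((a − 1)²Var(Ω) + sd²). The group acceleration is
   applied on the *prediction* scale here, so injected separations pass
   intact into raw and offset-adjusted deltas (and divided by the fitted
   slope under rescaling, leaving standardized effect sizes invariant);
   this is the configuration in which group-contrast recovery has known
   truth.

Two frozen presets encode the study conditions:

* `TRAINING_BIAS_PRESET` (a = 0.3, pivot = 71.43 y, sd = 5.13 y): training-set bias
  geometry. Derivation: slope a − 1 = −0.7; intercept 0.7·71.43 = 50.0;
  r = −0.7·13.57/sqrt(0.49·184.1 + 5.13²) = −0.880. The noise SD is the
  unique value putting r at −0.88 given the other two parameters.
* `GROUP_CONTRAST_PRESET` (same geometry, sd = 3.44 y): independent-test
  clinical contrasts. The within-group SD is fixed by requiring an AD
  acceleration of 4.1 y to standardize to Cohen's d = 1.19
  (4.1/1.19 ≈ 3.44); the MCI acceleration of 2.0 y then lands at d ≈ 0.58,
  and the omnibus ANOVA F at n = 75/561/362 lands near 65 with df (2, 995).

What the generator does **not** emulate: realistic SUVR covariance between
regions (features are conditionally independent), nonlinear aging
trajectories, site/scanner effects, sex structure, and non-uniform age
distributions. Passing tests therefore demonstrate correctness of the
estimation and adjustment *machinery* under the linear-bias mechanism, not
performance on real imaging cohorts.

## Regression backends

The primary backend is epsilon-insensitive SVR with a linear kernel and
the common library defaults, pinned explicitly (C = 1.0, epsilon = 0.1)
and recorded in the output metadata. Features are standardized by
training-set mean/SD before SVR (it is scale-sensitive); the
standardization is part of the fitted handle and is re-learned inside
every CV fold, never from test data. An OLS backend is provided so that
every bias-adjustment and evaluation test can be run independently of SVR
specifics; standardization leaves OLS predictions unchanged. Missing
feature values are rejected rather than imputed. Fold assignment is a
seeded random partition with sizes differing by at most one, without
stratification.

## Adjustment schemes

The offset model is fitted on **out-of-fold** CV deltas rather than the
final refit model's in-sample deltas: in-sample residuals are
optimistically small and would understate the bias line that independent
data will exhibit. The provenance of the fitting predictions is recorded
in the serialized model. The fitted model is frozen before any test-set
prediction is computed (in the pipeline, offset JSONs are written before
test data are predicted), since refitting on test data would leak the test
ages into the correction.

Rescaling divides by the fitted slope, so a floor |α| ≥ 0.05
(configurable) guards against variance blow-up; a fit below the floor is
flagged unusable rather than silently applied.

Identities used by the test suite, all consequences of OLS algebra on the
fitting set: adjusted deltas are exactly orthogonal to age under both
schemes (the rescaled delta is the predicted-on-age residual divided by
α); Var(offset-adjusted Δ) ≤ Var(raw Δ); Var(rescaled Δ) =
Var(offset-adjusted Δ)/α², hence strictly larger whenever |α| < 1; and the
delta-on-age slope equals the predicted-on-age slope minus one.

The covariate group comparison is implemented as the standard ANCOVA form:
Δ on group indicators plus age, with the group effect tested by the
partial F between nested models and group means reported at the pooled
mean age. No interaction terms are included.

## Statistical conventions

* R² is the squared Pearson correlation between chronological and
  predicted age. This affine-invariant definition is what makes R²
  provably identical before and after rescaling.
* Levene's test centers at the group mean (classic form);
  `center="median"` gives Brown–Forsythe.
* The bootstrap MAE comparison is a paired, seeded percentile bootstrap
  (default 1000 resamples): both methods' errors are resampled on the same
  subject indices; the two-sided p is 2·min(P(diff ≤ 0), P(diff ≥ 0)) with
  a +1/(n_boot + 1) continuity guard, so the smallest attainable p is
  2/(n_boot + 1) and p is never zero. A CI-overlap rule was deliberately
  not used — overlap of two marginal CIs is not a defined test for paired
  data. Null calibration of both this test and Levene's is verified by
  simulation in the acceptance suite (rejection rate within 5% ± 2%).
* Bootstrap CIs are percentile (not BCa), seeded; every random procedure
  records its seed in the report.
* One-way ANOVA df are (groups − 1, n − groups); Tukey HSD provides
  family-wise adjusted pairwise p-values. Cohen's d uses the
  (n − 1)-weighted pooled SD.

## Pipeline determinism and problem sizes

One master seed derives every stage seed by fixed documented offsets
(generator +1, split +2, folds +3, bootstraps +4, modulo 2³¹), so stages
can be re-run in isolation and identical configurations produce
byte-identical report bundles (JSON written with sorted keys; tables as
CSV). The default experiment uses the full study-scale composition
(750/561/362, 90/10 split, 10 folds, 1000 bootstrap resamples) and runs in
seconds; simulation-based tests use 100–1000 replicates at n = 675, sizes
chosen to keep Monte-Carlo error an order of magnitude below the tolerance
being asserted.

## Known limitations

* The linear offset basis is the only one offered; a nonlinear bias would
  require extending the offset regression basis.
* Group-contrast recovery through the feature path is attenuated (see
  above); calibrated contrast experiments therefore use the prediction
  simulator.
* The ANCOVA group test assumes a common Δ–age slope across groups; no
  slope-heterogeneity diagnostics are provided.
* Degenerate inputs (constant age, a single subject, zero pooled SD,
  near-zero rescaling slope) raise typed errors rather than returning
  NaNs; callers orchestrating many small groups should expect exceptions,
  not sentinels.
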