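# Methods

## Setting

External validation of a fixed clinical risk model: each patient carries a
EuroSCORE II predicted in-hospital mortality `x` (percent, in (0, 100]) and a
binary in-hospital death outcome. The score's 18 underlying covariates are
never refitted; the score is treated as a given scalar. Analyses are run for
the on-pump (ONCAB) and off-pump (OPCAB) CABG groups separately and pooled.
All score handling is on the percent scale; probabilities in [0, 1] appear
only transiently inside statistical routines. Presentation rounding is 2
decimal places; computation is at full precision.

## Discrimination

AUC uses the midrank Mann–Whitney convention (ties count ½), identical to
trapezoidal integration of the empirical ROC curve. The default 95% CI and
the two-sided test of AUC = 0.5 use DeLong's placement-value variance
estimator,

    var(AUC) = S10/m + S01/n,

with `S10`, `S01` the sample variances (n−1 denominator) of the positive and
negative placement values and `m`, `n` the death/survivor counts. DeLong is
deterministic and the standard choice for clinical validation; a stratified
percentile bootstrap (2000 resamples by default, mandatory seed) is provided
as an alternative. The p-value is a normal test on the DeLong standard error;
with perfect separation the variance collapses to 0 and the p-value is
reported as 0 (1 at AUC = 0.5) rather than undefined.

A strictly increasing score transform cannot reorder patients, so it leaves
the AUC bit-identical. `auc_invariance_check` verifies this to 1e−12 after
first confirming monotonicity of the correction (its derivative `a + 2bx` is
linear, so checking the two endpoints of the score range suffices).

## Calibration

- **O/E ratio**: observed mortality % divided by mean predicted %. Reported
  as observed/expected throughout; 1.0 is ideal, above 1 means
  underprediction.
- **Expected deaths**: `sum(x_i)/100`, equivalently `n · mean(x)/100`.
- **Hosmer–Lemeshow**: patients sorted by predicted risk and cut into
  near-equal groups (quantile assignment, ties kept together; the default is
  10 groups — deciles of risk; 4 matches the quartile audit). Statistic

      H = Σ_g (O_g − E_g)² / (E_g (1 − E_g/n_g)),

  algebraically the two-cell (death + survival) chi-square per group. Groups
  with expected deaths of exactly 0 or n_g have an undefined contribution and
  are merged into a neighbour with a warning. Degrees of freedom default to
  g (external validation of a fixed model); g − 2 is available for the
  development setting. Under correct calibration the test's type-I error at
  α = 0.05 sits in the low-to-mid single digits per cent (checked by
  simulation, 200 replicates of n = 5000).
- **Quartile audit**: the observed score range is cut at the empirical
  quartiles (half-open on the left, last interval closed), or at fixed,
  externally supplied cut points such as 0.88 / 1.92 / 3.05 / 5.14%; each
  row reports n, observed %, mean predicted % and O/E. Row counts, observed
  deaths and expected deaths are conserved exactly. Fully tied scores
  collapse the cut points; the audit then warns and returns the effective
  bins rather than fabricating empty ones.

## Recalibration

The correction family is multiplicative quadratic in the original score:

    mod(x) = x (a + b x),   a dimensionless, b per percent.

It fixes mod(0) = 0 structurally (no intercept: a zero score must stay zero)
and is linear in (a, b), so every estimator is closed-form least squares:

- `per_patient` (default): OLS of `100·died` on regressors `(x, x²)` without
  intercept. The simplest estimator linear in the parameters and consistent
  for the calibration curve within the family; standard errors come from the
  OLS covariance (the Bernoulli outcome is heteroscedastic, so these are
  approximate — adequate for the ±3 SE recovery checks used here).
- `binned`: WLS of bin observed mortality % on bin means of `(x, x²)`,
  weights equal to bin sizes, bins being deciles of the score.
- `constrain_oe`: either objective minimised subject to
  `Σ mod(x_i) = 100 Σ died_i`, i.e. exact cohort O/E = 1.0, via a single
  Lagrange step off the unconstrained solution:
  `β* = β̂ + Qc (d − c'β̂)/(c'Qc)` with `Q = (X'WX)⁻¹`, `c = (Σx, Σx²)`.
  The restricted covariance is `A cov(β̂) A'`, `A = I − Qcc'/(c'Qc)`. The
  constraint can only increase the objective, never decrease it.

Monotonicity of the fitted parabola is **checked, not enforced**, over the
observed score range; a warning is raised when the curve turns over inside
it (common in small cohorts whose upper tail holds few deaths). Application
clamps corrected scores into [0, 100] with a warning; the fit itself is
unconstrained to stay closed-form. When validating a correction, predictions
clamped to exactly 0% or 100% are nudged 0.001 inside the interval for the
grouped chi-square (cells at the bounds are degenerate); if the correction
is non-monotone on the cohort range the AUC-invariance check is aborted and
recorded as undetermined rather than failing the whole audit.

Degenerate inputs: a cohort with no deaths yields the exact all-zero fit
(with a warning); all-identical scores make the normal equations singular
and are rejected.

## Synthetic cohorts

The generator emulates the validation population that motivated the package,
since the source registry is access-restricted:

- **Scores**: log-normal truncated by inverse-CDF sampling. Defaults —
  on-pump log-mean ln 2.9, log-sd 0.85, truncation [0.88, 83.14]%;
  off-pump log-mean ln 2.7, log-sd 0.82, truncation [0.88, 69.33]%. These
  place roughly 70% of scores in the 1–5% band with a long right tail over
  the observed score ranges, the distribution features the validation tests
  rely on; the implied truncated means (≈4.4% and ≈4.0%) sit somewhat below
  the study means of 5.06% and 4.61% — matching the 1–5% mass and the range
  was prioritised over matching the mean exactly, since the full histogram
  is not available to fit.
- **Outcomes**: Bernoulli with `p(x) = x(a_true + b_true·x)/100`, i.e.
  miscalibration lives in the same family the recalibration fits, which
  makes coefficient recovery a well-posed end-to-end check. Defaults:
  on-pump `(1.6545, −0.0067)` (true O/E ≈ 1.5–1.6 under the default score
  distribution), off-pump `(0.98, 0)` (true O/E = 0.98 by construction).
  Configurations whose `p(x)` leaves [0, 1] anywhere on the truncated
  support (endpoints and interior vertex checked) are rejected at
  construction.
- **Reproducibility**: one named `numpy` generator per cohort; all score
  draws are consumed before any outcome draw, so score samples are invariant
  to outcome-model changes. `paper_like_pair` derives independent child
  seeds for the two groups from the single user seed.

What passing on these cohorts does **not** show: robustness to covariate
structure (comorbidities are not simulated), to secular trends in surgical
volume or case mix, to informative missingness, or to score distributions
outside the log-normal family. The generator matches moments and range, not
the unpublished histogram bin counts.

## Problem sizes and numerical choices

Parameter-recovery checks run at n = 2·10⁵ (OLS standard errors there give
±0.05 on `a` and ±0.005 on `b` as 3σ bands); law-of-large-numbers and
AUC-invariance checks at n = 10⁵; the type-I-error simulation at 200
replicates of n = 5000; brute-force AUC cross-checks at n ≤ 200 — sizes at
which the checks are sharp while the whole suite stays fast. Exact
assertions (AUC invariance, constrained O/E, conservation identities) use
tolerances of 1e−10 to 1e−12, i.e. floating-point noise only.

## Known limitations

- The correction is a population-level rescaling; it cannot repair poor
  discrimination, only the calibration level and shape within its quadratic
  family.
- OLS on a binary outcome is not efficient (a weighted or logistic-scale
  variant would be); it is used because the published procedure is plain
  least squares and the estimator stays closed-form and unbiased within the
  family.
- The quadratic family is monotone only up to `−a/(2b)` when `b < 0`;
  extrapolating a fitted correction beyond the observed score range is
  unsafe, which is why the fitted `valid_range` travels with the model and
  the nomogram refuses (or the pipeline caps) grids beyond the monotone
  span.
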