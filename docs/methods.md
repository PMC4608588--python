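# Methods

## Model

`dlogit` fits a two-group discrimination function from a stratified
training sample of n₀ labeled controls and n₁ labeled cases when the
control stratum is contaminated by mislabeled cases.  The true status y is
assumed logistic, P(y = 1 | x) = expit(β₀ + βᵀx), and the mislabeling
probability λ = P(z = 0 | y = 1) is assumed constant across covariates.
The observed label z then follows a zero-inflated Bernoulli model whose
success curve is the logistic scaled by (1 − λ) — a *defective* logistic
curve with asymptote 1 − λ.  Because P(y = 1) = P(z = 1)/(1 − λ), the
expected number of mislabeled rows in the control stratum is n₁·λ/(1 − λ).

Assumptions worth stating explicitly:

* **One-sided noise.** Every z = 1 row is a true case.  If contamination
  runs the other way, swap the label coding (the CLI `--flip` flag).
* **λ independent of x.** Covariate-dependent mislabeling is out of scope.
* **The logistic link is correct.** The contamination parameter is
  identified by the shape of the upper tail of P(z = 1 | x): it is
  estimated, loosely, from labeled controls whose covariates make
  P(y = 1 | x) close to 1.  Link misspecification therefore biases λ̂, and
  a fitted λ̂ > 0 can reflect lack of fit rather than mislabeling.  The
  decision to use the defective model should rest on prior knowledge that
  mislabeling occurs, not on the test of λ = 0 alone.
* **Case-control sampling.** The intercept absorbs the design's mixing
  proportions; slopes are design-independent, but predicted probabilities
  must be interpreted relative to the n₀:n₁ design.

## Parameterization and numerics

The canonical internal parameter is μ = λ/(1 − λ) ∈ [0, ∞): its boundary
is a plain 0, its profile likelihood is more symmetric than λ's, and n₁·μ
is directly the expected mislabeled count.  All probability and
likelihood code works in the log domain: with q = expit(−η),

    log P(z=1|x) = log_expit(η) − log(1 + μ)
    log P(z=0|x) = log(μ + q) − log(1 + μ),  log(μ + q) via logaddexp,

so neither |η| up to ±700 nor μ at the boundary produces a spurious
log(0).  The gradient is analytic and formed from the same log-domain
quantities.

## Estimation

* **Start.** The plain logistic MLE (statsmodels `Logit`) with μ = 0.
  Since the defective model nests the logistic one, the achieved
  log-likelihood is never below the logistic fit's.
* **Optimizer.** L-BFGS-B over (μ, β₀, β) with μ ≥ 0; relative
  function tolerance 1e−12, gradient tolerance 1e−9, at most 500
  iterations.  An optional cap λ ≤ n₀/(n₀ + n₁) (the largest contamination
  consistent with the observed label split) is translated to the μ scale
  when requested.
* **Rank check.** Pivoted-QR rank check of the intercept-augmented design
  before fitting; rank deficiency and separation raise errors naming the
  offending columns rather than returning garbage.
* **Standard errors.** Inverse of the observed information obtained by
  central finite differences of the analytic gradient, step
  eps^(1/3)·max(1, |θⱼ|) per coordinate, symmetrized.
* **Boundary handling.** If μ̂ < 1e−6 the fit is flagged `boundary`,
  λ̂ is reported as exactly 0, and the μ standard error is suppressed
  (information is computed for the regression block at μ = 0, so the
  coefficient SEs survive).  Standard asymptotics assume the true λ lies
  away from the boundary; at the boundary the Wald test refuses to run and
  points the user at the likelihood-ratio test or the profile likelihood.
* **Profile likelihood.** For each λ on a grid in [0, n₀/(n₀+n₁)] the
  likelihood is maximized over (β₀, β) only, warm-starting each grid point
  at the previous solution; per-point failures are recorded, not fatal.

## Inference

* **Wald test of λ = 0** is one-sided by default (upper-tail normal on
  μ̂/SE): μ ≥ 0 by construction, so the alternative is one-sided.  A
  two-sided version is available.
* **Likelihood-ratio test** uses the deviance difference against χ²₁.
  Under the boundary null the plain χ²₁ reference is conservative; the
  0.5·χ²₀ + 0.5·χ²₁ mixture (which halves the p-value) is available via
  `boundary_mixture=True`.  Every result carries a note that the null sits
  on the boundary.
* **Mislabeled-count interval**: Wald on the μ scale, μ̂ ± z·SE(μ̂), scaled
  by n₁ and truncated below at 0 (truncation and scaling commute).
  Reported counts are rounded half away from zero.

## Prediction and classification

Labeled controls are scored with the posterior
P(y = 1 | z = 0, x) = λp/(1 − (1 − λ)p), p = P(y = 1 | x); rows already
labeled case are scored with P(y = 1 | x) itself.  Classification uses a
strict inequality at the cutoff, so ties are classified as control.  ROC
curves are standard empirical curves over all distinct thresholds with
trapezoidal AUC (computed via scikit-learn and cross-checked against a
Mann–Whitney identity in the tests).  Every report repeats the caveat that
the intercept reflects the design's mixing proportions.

## Synthetic data

The generator reproduces the sampling scheme the model assumes: covariates
from per-column distributions (normal, Bernoulli, categorical), true
status from the logistic model, rejection sampling per stratum to exactly
n₀ true controls and n₁ true cases (erroring after drawing 1000× the
target without filling a stratum), z = y, then contamination — either an
exact count k of uniformly chosen cases relabeled, or each case
independently with probability λ.  A single integer seed drives
everything; replicate substreams come from `SeedSequence.spawn`, so
replicate r is unchanged when the number of replicates grows.

Because sampling is stratified, the identified intercept is not the
population β₀ but β₀ + log(n₁/n₀) − logit(π₁), with π₁ the marginal case
probability under the covariate distribution; the recovery experiment
judges intercept bias and coverage against this design-adjusted value
(computed by Monte Carlo on a fixed substream, exact when there are no
covariates).

What the generator does **not** emulate: real risk-factor structure
(correlated covariates, nonlinearities beyond what the user encodes),
link misspecification, covariate-dependent mislabeling, or missing data.
Passing simulation tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness on real studies —
where, e.g., the probability of disease rarely truly approaches 1 and λ̂
absorbs some lack of fit.

### Study conditions used by the tests and the acceptance script

* **Emulated case-control study** (`example_study_config`): 200 true
  cases, 776 true controls, a standardized continuous risk score
  (N(0, 1), slope 1.5) and a binary exposure (Bern(0.35), slope 1.0),
  intercept −2.0, and 67 cases relabeled — sample sizes and contamination
  count chosen to mirror a classical cancer case-control design with
  artificially known mislabeling; effect sizes chosen to give
  the strong discrimination typical of such studies (control-group
  AUC ≈ 0.85).
* **Repeated-contamination study**: 100 relabelings of 67 cases with
  refits; the median and IQR of n₁·μ̂ characterize the estimator's
  sampling distribution.  At n ≈ 1000 this distribution is wide and has an
  atom at 0 — single-draw estimates of the mislabeled count should be
  read with the interval, never alone.
* **Parameter recovery**: λ = 0.25, β₀ = −1, β₁ = 1, 2000 per stratum,
  200 replicates; mean λ̂ is unbiased to within Monte-Carlo error and Wald
  95% coverage for the coefficients sits near nominal.  With λ = 0 truth,
  μ̂ piles up at the boundary in roughly half the replicates, as one-sided
  boundary asymptotics predict.

These problem sizes keep the full test suite and the acceptance script in
the tens of seconds while leaving Monte-Carlo error well below the
assertion tolerances.

## Known limitations

* Wald intervals for n₁·μ can be poor near the boundary (the lower limit
  truncates at 0); profile-likelihood intervals are available through
  `profile_lambda` but not automated.
* No penalized estimation: with many covariates relative to n the
  likelihood surface for (β, λ) is weakly identified and regularization of
  β (not λ) would be needed.
* Only the logistic link is implemented; zero-inflated complementary
  log-log (natural for imperfect-sensitivity serology) would be a
  straightforward extension of the same likelihood code.
* The EM/latent-label formulation and two-sided label noise are out of
  scope.
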