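# Methods

## The valuation problem

`cvwtp` estimates household willingness to pay (WTP) for a non-market
good — here, conservation of a threatened wild species funded by an
annual tax — from a two-part stated-preference questionnaire:

1. **Participation.** A yes/no question on whether the respondent would
   pay the tax at all.
2. **Multiple-bounded payment card.** Respondents who said yes react to
   a fixed ladder of nine amounts (EUR 1, 5, 10, 20, 40, 80, 150, 300,
   500), stating at each amount how certain they are about paying:
   *definitely yes*, *probably yes*, *not sure*, *probably no*,
   *definitely no*.

The analysis follows the random-utility tradition: stated answers
reveal a latent monetary valuation plus stochastic taste variation.

## Stage 1 — participation logit

P(yes) = logistic(β₀ + Xβ), fitted by Newton maximum likelihood
(statsmodels backend). Reported quantities mirror standard practice for
participation models:

- odds ratios exp(β) with 95% Wald intervals;
- marginal effects **at covariate means**, with binary covariates as a
  0→1 discrete change (average marginal effects available behind
  `kind="average"`, non-default);
- Nagelkerke pseudo-R², −2 log L, AICc with k counting the intercept,
  and percent correctly classified at cutoff 0.5 (ties predict "yes").

Complete separation is detected (diverging coefficients or perfect
in-sample prediction) and raised as an error naming the covariate,
because the reported Wald quantities are meaningless there.

## Stage 2 — certainty recoding and interval likelihood

The certainty grid is collapsed to yes/no per amount at a chosen
certainty threshold (Welsh–Poe style). The default `probably_yes`
scheme maps {definitely yes, probably yes} → yes; `definitely_yes` and
`not_sure` schemes are available. Larger yes-sets can only move each
respondent's bracket upward, a monotonicity the tests enforce.

The recoded answers bracket latent WTP between the highest accepted
amount A^L (0 if none accepted) and the lowest refused amount above it,
A^U (∞ if none), so A^L ≤ WTP < A^U. Internally inconsistent patterns
(a refusal below an acceptance) are handled by this *envelope rule* and
flagged; a config switch drops them instead. Left-censored respondents
(no amount accepted) are kept in the likelihood with bracket
[0, lowest bid) rather than discarded.

With a log-logistic WTP distribution — CDF logistic in log-amount,

    F(A) = 1 / (1 + exp(δX − α ln A)),  α > 0,

the sample log-likelihood is Σᵢ ln[F(Aᵢ^U) − F(Aᵢ^L)] with F(0) ≡ 0 and
F(∞) ≡ 1. δ is the covariate vector (intercept included); α, the bid
coefficient, is the marginal utility of money. Median WTP at covariate
point x̄ is exp(δx̄ / α).

### Numerics

- Optimization over (δ, ln α) keeps α positive. BFGS with the analytic
  gradient runs first; because quasi-Newton line searches stall on
  precision loss near the optimum, a damped Newton polish (Hessian
  differenced from the analytic gradient) then drives the gradient
  sup-norm below 1e−6, the convergence criterion.
- Each bracket's log-mass is computed stably as
  `log1p(−e^{a−b}) + log_expit(b) + log_expit(−a)` with a = α ln A^L − δX,
  b = α ln A^U − δX; vanishing masses are floored at −700 with a warning
  counter instead of propagating −∞.
- Identical (bracket, covariate) rows are collapsed to weighted rows
  before optimization — an exact reformulation that makes bootstrap
  refits cheap.
- Starting values: α₀ = 1 and δ₀ from least squares of ln(midpoint) on
  X, midpoint = geometric mean of the bounds (A^U/2 when left-censored,
  2·A^L when right-censored).
- The parameter covariance is the inverse observed information on the
  (δ, α) scale, differenced centrally from the analytic gradient.
- A dataset whose every bracket is (0, ∞) is rejected as
  non-identifiable.

### Mean WTP

Three estimators of the mean at covariate point x̄ (default: means over
the fitted subsample):

- `closed_form` (default): exp(δx̄/α) · (π/α) / sin(π/α), the
  log-logistic mean, defined only for α > 1. For α ≤ 1 the mean
  diverges; the error advises the truncated estimator, and the pipeline
  falls back to it automatically with a logged warning.
- `truncated_at_max_bid`: ∫₀^top-bid S(A) dA, the survival integral cut
  at the largest card amount — conservative and always defined.
- `printed_eq4`: exp(δx̄/α + 1/(2α²)), a log-normal-style variant kept
  for comparability with reports whose printed mean formula is
  typographically ambiguous; it is never the default.

### Bootstrap and aggregation

95% CIs for mean WTP come from a nonparametric respondent-level
percentile bootstrap (default B = 1000, seed mandatory in the pipeline
config). Resampling respondents with replacement is realized as
multinomial reweighting of the unique response patterns —
distribution-identical and much faster. Each replicate refits the model
(warm-started at the full-sample estimate) and re-evaluates the mean at
the replicate's covariate means. Replicates failing to converge, or
with α ≤ 1 under the closed form, are dropped and counted; more than
10% failures marks the CI unreliable. A fully degenerate dataset (one
unique response pattern) leaves the two-parameter model unidentified,
so such data produce an explicit error rather than a sham zero-width
interval.

Population revenue = mean WTP × share of willing payers × number of
paying units (households), with CI bounds scaled by the same product.
The willing share defaults to the first-stage sample proportion; a
config override supports report-only arithmetic from externally
supplied numbers (`cvwtp aggregate`).

## Scales and diagnostics

Psychometric predictors (attitude, knowledge, conservation-action
intention, moralistic and dominionistic worldviews) are scored as
reverse-coded item means on the raw 1–5 metric: reproducible,
metric-faithful, and rank-equivalent to first-component scores for a
one-factor battery. Factor extraction and confirmatory fit indices are
deliberately out of scope. Reliability is Cronbach's alpha with
corrected item-total correlations and alpha-if-deleted, all with
sample (n − 1) variances.

Collinearity screening mimics the common stepwise-VIF workflow: the
covariate with the largest VIF ≥ 5 is removed and VIFs recomputed until
all pass; exact linear dependence surfaces as an infinite VIF.
Binary/ordinal covariates enter the auxiliary regressions as numeric.
Spearman rank correlations (average-rank ties) are reported against a
0.7 threshold without significance tests.

## Synthetic surveys

The generator reproduces the statistical structure the analysis
assumes, with every draw a pure function of (config, seed):

- **Covariates.** Composite predictors are drawn from moment-matched
  truncated normals on [1, 5] (and the declared supports for age and
  income). Two Table-level moment targets — a ceiling-effect scale with
  mean 4.79/SD 0.49 and a floor-effect scale with mean 2.05/SD 1.29 —
  lie outside the truncated-normal family's reachable set (its maximum
  SD at those means is about 0.21 and 1.05), so the sampler falls back
  to a moment-matched scaled Beta there. Ordinal recreation-frequency
  covariates use fixed categorical probabilities approximating survey
  moments (exact matching is impossible on an integer 1–5 support).
  Raw Likert items are then scattered around each latent composite
  (Gaussian noise, rounded, clipped, reverse-stored for reverse-coded
  items) so generated CSVs carry the full questionnaire.
- **Participation.** y ~ Bernoulli(logistic(β₀ + Xβ)); default
  β₀ = logit(0.616) with zero slopes.
- **Latent WTP.** W drawn by inverse-CDF from the log-logistic with
  linear predictor δX and shape α; defaults δ₀ = α·ln 40 (median
  EUR 40) and α = 1.8, with zero slopes.
- **Certainty grids.** The log acceptance margin m = ln W − ln A is
  banded into the five levels at thresholds (0.5, 0, −0.5, −1.0). The
  yes/no side is decided by the noiseless margin at the second
  threshold, while per-respondent Gaussian jitter (σ = 0.25) shifts the
  refinement *within* each side. Consequences: all five levels occur
  (concentrated near the threshold, as response uncertainty should be),
  grids are monotone down the ladder, and the probably-yes recoding
  reproduces W ≥ A exactly — so the default scheme estimates the true
  parameters without attenuation. This is a minimal response-psychology
  model chosen for testability, not a behavioral claim.

What the generator does **not** emulate: protest zeros and strategic
answers, item nonresponse, interviewer effects, non-monotone raw grids
(the envelope rule is exercised by constructed patterns in the tests
instead), and correlation between covariates. Passing tests therefore
demonstrate internal statistical correctness of the estimators under
the assumed model, not robustness to real-world response anomalies.

## Problem sizes used in validation

Single-run parameter recovery uses n = 2000 respondents (~1200 in the
second stage) with every coefficient checked within 3 standard errors;
replication bias uses 200 independent n = 2000 surveys (median absolute
error of the second-stage intercept and shape below 3% of truth);
bootstrap coverage uses 200 surveys of n = 500 with B = 300 replicates,
accepting empirical coverage between 90% and 99%. The closed-form mean
is cross-checked against Monte-Carlo draws from an independent
log-logistic implementation.

## Known limitations

- Interval-censored ML assumes the recoded yes/no answers are exact
  expressions of W ≥ A; certainty miscalibration (e.g. yea-saying)
  biases α downward and the mean upward.
- The closed-form mean is sensitive to α near 1; with fat-tailed fitted
  distributions the truncated estimator is the honest summary.
- Marginal effects at means are not average marginal effects; for
  heavily skewed covariates the two can differ noticeably (both are
  available).
- Composite scoring as item means assumes a one-factor battery with
  roughly equal loadings; strongly multidimensional batteries should be
  re-scored externally and passed in as covariates.
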