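# Methods

## The problem

In delayed-entry ("left-truncated") cohort studies, subjects come under
observation at a time `L` after the natural time origin, and only those
whose event time exceeds `L` can ever be sampled.  Long survivors are
over-represented, and so are the covariate values associated with long
survival.  When a baseline covariate is additionally missing for part of
the sample — often by design, when the measurement is invasive or costly —
the analyst faces two interacting selection effects: truncation biases the
sample covariate distribution, and missingness biases the complete-case
subsample.

`ltrcmiss` implements and compares the standard missing-covariate
strategies for the Cox proportional-hazards model under this sampling
scheme, for the case of a binary covariate of interest `X` and fully
observed categorical covariates `W`.

## Analysis model and estimators

The outcome model is the Cox model

    h(t | X, W) = h0(t) exp(beta1 X + beta2' W),

fitted by the partial likelihood with the risk-set adjustment for delayed
entry: the at-risk indicator is `Y*_i(t) = I(L_i < t <= T_i)` (strict at
entry, closed at exit).  Ties are handled with the Breslow approximation;
simulated event times are continuous so ties have probability zero.
Newton–Raphson with step halving (up to 10 halvings) maximises the
weighted partial likelihood; a coefficient excursion past |beta| = 20
aborts with a monotone-likelihood diagnostic.  The default covariance is
the inverse observed information.

* **Complete case (CC)** drops subjects with missing `X`.  Consistent
  under missingness unrelated to the outcome; biased when missingness
  depends on the observed time or event indicator.
* **IPW** weights complete cases by `1 / pi_i`, where
  `pi_i = P(R_i = 1 | ...)` comes from a user-specified logistic model
  (terms from `{1, delta, sqrtT, w<k>, lateT, lateL}`).  Its standard
  error is a robust sandwich built from per-subject score residuals; the
  naive inverse of the weighted information is smaller by roughly the
  root of the mean weight and produced badly anticonservative intervals
  in our experiments, so it is not used for weighted fits.
* **MI** imputes the missing binary covariate from the conditional law
  implied by the Cox model.  When `logit P(X=1|W)` is logistic, the
  conditional law of `X` given `(W, T, delta)` is again logistic with
  predictors `W`, `delta`, `H0(T)` and `H0(T) x W`; the unknown `H0(T)` is
  replaced by the Nelson–Aalen estimate of the marginal cumulative hazard,
  computed once on the full sample with truncation-adjusted risk sets.
  Each of `m = 100` imputed datasets is analysed with the truncated Cox
  model and pooled with Rubin's rules (classical Rubin degrees of freedom;
  no small-sample correction — at n = 300 it is immaterial).
* **AIPW** solves an augmented estimating equation that combines the
  `R/pi`-weighted complete-case Cox score with an augmentation term built
  from the posterior `P(X = 1 | T, delta, W)`.  The posterior multiplies
  the covariate-model prior by the Cox likelihood factor
  `exp(lp_x)^delta * exp(-H0(T) exp(lp_x))`; the baseline-hazard factor
  common to both values of `x` cancels.  The estimator is doubly robust:
  consistent when either the missingness model or the covariate model is
  correct.

## AIPW algorithm

No closed-form solver exists for the coupled system (Cox coefficients
`beta`, covariate-model parameters `eta`, baseline hazard `H0`), so the
package uses an alternating scheme initialised at the complete-case
truncated Cox fit and complete-case logistic ML for `eta`:

1. refresh the posteriors `P(X=1 | T, delta, W)` at the current
   parameters;
2. re-solve the `eta` score equation (a logistic score whose incomplete
   subjects contribute their posterior-expected score, weighted
   `1 - R/pi`);
3. rebuild the posterior-mixed at-risk sums `S^(m)` and the Breslow-type
   baseline hazard `H0(t) = n^-1 sum I(T_i <= t) delta_i / S^(0)(beta, T_i)`;
4. take one Newton step on `beta`.

The augmentation term is evaluated in closed form at each subject's own
observed time: conditioning on `(T_i, delta_i)` makes the counting-process
integral a point mass at `T_i` when `delta_i = 1` and zero otherwise.

Convergence is declared when the estimating-equation residual norm falls
below 1e-6 (or the joint parameter change does).  Under a misspecified
covariate model the plain alternation can enter a small limit cycle; a
non-decreasing residual therefore halves an adaptive damping factor on the
`beta` step (floor 1/64), which in practice collapses the cycle within a
few iterations.  The iteration cap is 300.  AIPW interval estimates use a
subject-level bootstrap (resample n with replacement, refit the pi model
and the whole AIPW procedure); non-converged replicates are dropped and
counted, and more than 20% failures aborts the bootstrap.

## Imputation-model estimation under quasi-separation

The imputation design (intercept, three W indicators, `delta`, `H(T)`,
three `H(T) x W` interactions) is fitted on roughly 150 complete cases in
the reference setting, with only ~10–15 censored subjects among them.
Quasi-separation is routine: plain ML produced |coefficients| near 20 in
about a quarter of replicates, and proper-MI redraws from the resulting
normal approximation inject so much imputation noise that the pooled
hazard ratio is visibly attenuated.  The package therefore fits the
imputation model with the data-augmentation stabiliser of White, Daniel &
Royston: for every predictor, pseudo-observations at the predictor's mean
± 0.5 SD (other predictors at their means, values clamped to the observed
range) paired with both outcome values, the pseudo-rows sharing total
weight p + 1.  Proper coefficient redraws on top of the augmented fit are
the default (`proper=False` imputes at the fitted coefficients and
understates the between-imputation variance).  This combination was the
only one of the stabiliser/redraw variants we evaluated whose bias *and*
variance behaviour is simultaneously coherent across truncation levels;
the choice matters at the first decimal of the pooled estimate under heavy
truncation, which is worth knowing when comparing MI implementations.

## Synthetic data

The simulator reproduces a delayed-entry biomarker cohort:

| quantity | law | default |
|---|---|---|
| W1..W3 | iid Bernoulli(0.5) | — |
| X given W | logistic, `eta0 + eta1'W` | eta0 = 0.5, eta1 = (log 2, −log 2, log 1.5) |
| U (failure) | Cox with Weibull baseline `h0(t) = rho kappa (rho t)^(kappa-1)` | rho = 0.1, kappa = 0.5, beta2 = (log 2, −log 2, log 1.5), beta1 ∈ {log 2, log 4} |
| L (entry) | `c1 · Beta(6, 1.5)` | c1 calibrated to the truncation rate q ∈ {0, .15, .25, .5, .75}; `L ≡ 0` when q = 0 |
| C (censoring) | `c1 + Weibull(shape 4, scale c2)` | c2 calibrated to the censoring rate λ ∈ {0.1, 0.5}; C > L holds surely |
| R (observation of X) | MCAR (constant pi), `logit pi = a + log(4) delta`, or `logit pi = alpha0 − alpha1 sqrt(T)` with alpha1 = log 1.25 (λ=0.1) or log 3 (λ=0.5) | intercepts calibrated to the missingness rate θ ∈ {0.25, 0.5} |

`ceil(n / (1 − q))` subjects are drawn and those with `L >= T` removed, so
the retained size is random around n (trimming to exactly n would distort
the entry distribution).  Failure times use the closed-form inverse
`U = (1/rho)(−log u · e^{−beta'Z})^{1/kappa}`.  The truncation rate is
defined pre-removal as `P(L > T)`; censoring and missingness rates are
defined on the retained sample.

Calibration of `c1`, `c2` and the missingness intercept is by bisection on
Monte Carlo rate estimates (200 000 draws, absolute tolerance 0.005) with
common random numbers, in the dependency order c1 → c2 → intercept; the
constants are cached per scenario and use a fixed internal seed separate
from simulation seeds.  Because `L < C` surely, `P(L > T) = P(L > U)`, so
the entry scale can be calibrated before the censoring scale.

What the generator does *not* emulate: covariate-dependent entry
(`X ⊥ L | W` holds by construction, as the MI/AIPW posterior derivation
assumes), dependent censoring, ties, measurement error, or
missing-not-at-random mechanisms.  Passing tests therefore speak to
estimator behaviour under the stated sampling scheme, not to robustness
against violations of those assumptions.

## Study engine and problem sizes

`run_scenario` runs a scenario for a requested set of estimators with
per-replicate seeds spawned deterministically from a master seed, and
reports bias, percent bias, empirical SD, mean estimated SE, 95% coverage
and failure counts per method; failed replicates are excluded per method
and always counted.  Confidence intervals are Wald for CC/CD/IPW, Rubin-t
for MI, and normal-with-bootstrap-SE for AIPW (the bootstrap is off by
default inside scenario grids because it multiplies cost by the bootstrap
size; bias/SD columns do not need it).

`compare_tables` formalises agreement with published Monte Carlo
summaries: bias cells must fall within `2 · SD_printed / sqrt(reps)`,
SD/mean-SE cells within 15% relative, coverage cells within
`2 sqrt(0.05 · 0.95 / reps) + 0.02`.

Problem sizes: the acceptance suite runs 500 Monte Carlo replicates per
scenario with m = 100 imputations; the acceptance script reports at 300
replicates per scenario; calibration uses 200 000 draws.  Bias and
coverage bands scale as `1/sqrt(reps)`; the relative SD band does not, so
SD cells need the larger replicate counts to keep estimation noise well
inside the band.

## Numerical choices

* Cox Newton tolerance 1e-8 on the score sup-norm, max 50 iterations;
  rank of the centered design on the at-risk set is checked before
  iterating.
* Fitted missingness probabilities below 1e-6 raise (no silent weight
  truncation).
* Logistic ML fits go through IRLS and accept quasi-separated but finite
  solutions (as R's `glm` does); only genuinely non-finite estimates
  raise, with a hint to reduce the model.
* The Nelson–Aalen/Breslow step functions are right-continuous with value
  0 before the first jump; a zero at-risk count at an event time raises
  naming the time.
* `StepFunction` evaluation is by binary search; increments are validated
  nonnegative.

## Known limitations

* The IPW/AIPW variance treatments ignore the estimation of `pi`
  (sandwich and bootstrap respectively capture most, not all, of it).
* MI under severe truncation (q ≈ 0.75) is biased by design — the sample
  covariate distribution cannot estimate the population `P(X=1|W)` — and
  the package reports, rather than corrects, the accompanying
  overstatement of the MI standard error.
* No support for interval censoring, recurrent events, time-varying
  covariates or effects, stratified baselines, Efron ties, or
  missing-not-at-random mechanisms.
* The covariate-stratified refinement of the Nelson–Aalen imputation
  covariate is not implemented.
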