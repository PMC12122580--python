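# ltrcmiss

Cox proportional-hazards analysis of **left-truncated, right-censored
survival data with a partially missing binary covariate**.

## Who this is for

Delayed-entry cohorts are common in chronic-disease research: the clock
starts at diagnosis, but patients enrol later, and anyone who experiences
the outcome before they could enrol is never sampled.  On top of that,
expensive baseline measurements (a CSF biomarker, say) are often collected
for only part of the cohort.  `ltrcmiss` is for biostatisticians who need
to fit

    h(t | X, W) = h0(t) · exp(β₁ X + β₂ᵀ W)

when the sample is left truncated (handled by the risk-set adjustment
`Y*ᵢ(t) = I(Lᵢ < t ≤ Tᵢ)`) *and* the binary covariate X is missing for
some subjects (handled by one of four estimators):

| method | idea | when it works |
|---|---|---|
| CC   | drop incomplete subjects | missingness unrelated to outcome |
| IPW  | reweight complete cases by 1/π̂ᵢ, π̂ from a logistic model for P(X observed) | π model correct |
| MI   | impute X from its conditional law given (W, δ, Ĥ(T)); pool with Rubin's rules | imputation model correct **and** truncation mild |
| AIPW | augmented estimating equation with posterior P(X=1 \| T, δ, W) | *either* π *or* the covariate model correct (doubly robust) |

The package also contains a calibrated simulator of this sampling scheme
and a Monte Carlo study engine that reproduces the estimators'
bias/efficiency/coverage behaviour across truncation (γ up to 0.75),
censoring (10%/50%) and missingness (25%/50%) regimes — including the key
cautionary finding that **MI breaks down under heavy truncation** because
the selection-biased sample cannot estimate the population covariate
distribution.

## Worked example

```python
import numpy as np
import ltrcmiss as lm

# a delayed-entry cohort with 50% MCAR-missing X, truncation rate 0.25
cfg = lm.ScenarioConfig(n=300, q=0.25, lam=0.1, theta=0.5,
                        beta1=np.log(4), mechanism="MCAR")
sample, latent = lm.simulate_scenario(cfg, rng=7)
print(lm.summarize(sample))

cc   = lm.fit_cox(lm.complete_cases(sample))
ipw  = lm.ipw_fit(sample, lm.fit_pi(sample, ["1", "w1"]))
mi   = lm.mi_estimate(sample, m=100, rng=7)
aipw = lm.aipw_fit(sample, lm.fit_pi(sample, ["1", "w1"]))

print(f"CC   beta1 = {cc.beta[0]:.3f}  (se {cc.se[0]:.3f})")
print(f"IPW  beta1 = {ipw.beta[0]:.3f}  (se {ipw.se[0]:.3f})")
print(f"MI   beta1 = {mi.point[0]:.3f}  (se {mi.se[0]:.3f})")
print(f"AIPW beta1 = {aipw.beta[0]:.3f}")
```

prints

```
{'n': 288, 'events': 264, 'censoring_fraction': 0.0833..., 'missingness_fraction': 0.4097..., 'x_frequency_observed': 0.5470...}
CC   beta1 = 1.557  (se 0.200)
IPW  beta1 = 1.565  (se 0.184)
MI   beta1 = 1.518  (se 0.238)
AIPW beta1 = 1.643
```

The retained size (288) is random around n = 300 because truncation
removes a random number of subjects, and the realised missingness (41%)
fluctuates around its 50% target the same way.  All four estimates sit
within one standard error of the true log-hazard ratio log 4 ≈ 1.386 for
this single replicate, with MI closest here because imputation reuses the
incomplete subjects.  Monte Carlo summaries over many replicates (the
package's purpose) come from the study engine:

```python
metrics, replicates = lm.run_scenario(cfg, ["CC", "CD", "IPW", "AIPW", "MI"],
                                      reps=500, master_seed=42)
print(metrics[["method", "bias", "pct_bias", "sd", "mean_se", "coverage"]])
```

A command-line interface mirrors the library:

```bash
ltrcmiss simulate --config scenario.yaml --seed 11 --out sample.csv
ltrcmiss fit --method aipw --pi-formula "1+delta" --boot 500 --input sample.csv
ltrcmiss study --grid grid.yaml --reps 500 --seed 2024 --out results.csv
```

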