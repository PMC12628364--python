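# melsimpute

Two-step Bayesian multiple imputation for ecological momentary
assessment (EMA) data, built on mixed-effects location-scale models.

EMA studies prompt subjects several times a day ("beeps") and routinely
lose 20–40% of reports to non-response. Worse, the missingness is often
informative: subjects doing poorly, or whose behavior is more erratic,
respond less. Imputing such data with a model that assumes constant
within-subject (WS) variance and ignorable missingness biases both the
completed values and downstream estimates. This package is for
biostatisticians and behavioral researchers who need principled
imputations for subject × occasion longitudinal outcomes.

## Models

Three nested models can serve as the imputation engine for an outcome
y_ij (subject i, occasion j, covariates x_ij):

- **RILM** — random-intercept linear mixed model:
  y_ij | v0_i ~ N(β0 + x_ij'β + v0_i, e^{α0}), v0_i ~ N(0, σ_v0²).
- **MELS** — mixed-effects location-scale model: the WS variance becomes
  σ²_ε,ij = e^{α0 + x_ij'α + v1_i} with a random scale effect v1_i
  correlated with v0_i.
- **SPMELS** — shared-parameter MELS: a random-intercept logistic model
  for the missingness indicator, m_ij ~ Bern(logit⁻¹(τ0 + t_ij'τ + λ_i)),
  whose random missing effect λ_i ~ N(0, σ_λ²) loads on the outcome
  through v0_i = γλ_i + η0_i and v1_i = δλ_i + η1_i — linking
  missingness to both the level and the volatility of the outcome
  (missing-not-at-random).

Imputation is the classic two-step Bayesian scheme: draw θ (and subject
effects) from P(θ | y_obs) — NUTS for MELS/SPMELS, a maximum-likelihood
asymptotic-normal surrogate for RILM — then draw ŷ_miss from
P(y_miss | y_obs, θ), repeated L times. The share of a random effect's
variance explained by missingness is (γσ_λ)² / ((γσ_λ)² + σ_η0²).

## Worked example

```python
from melsimpute import (Scenario, generate_dataset, SPMELS, MCMCConfig,
                        sequential_impute, pool_mean, imputation_error,
                        variance_share)

scn = Scenario.base()                      # 20 subjects x 5 days x 6 beeps
gen = generate_dataset(scn, seed=3)        # ~20% of reports masked
fit = SPMELS(gen.data, loc_covariates=("x1", "x2")).fit(
    MCMCConfig(chains=2, warmup=400, draws=400), seed=6)
print(fit.summary().round(2)[["mean", "sd", "q2.5", "q97.5"]])

imps = sequential_impute(gen.data, {"x1": "spmels", "y": "mels"}, L=10,
                         seed=1, mode="fast",
                         mcmc=MCMCConfig(chains=1, warmup=300, draws=300))
pooled = pool_mean(imps)
print(imputation_error(pooled, gen.data))
```

Output (abridged):

```
scheduled occasions: 600 | missing: 21.0% | calibrated tau0: -2.448
              mean    sd  q2.5  q97.5
beta[x1]      0.49  0.04  0.41   0.57
alpha[x1]     0.19  0.06  0.06   0.31
gamma        -0.38  0.31 -1.02   0.22
delta         0.57  0.25  0.13   1.11
sigma_lambda  0.94  0.24  0.53   1.42
location-effect variance share from missingness: 13.6%
pooled imputation MSE: 0.569 | single-copy MSE: 0.972
```

Read: the mean effect of the time-varying covariate is 0.49 (truth 0.5);
`alpha[x1]` ≈ 0.19 says the WS variance grows with x1; γ < 0 and δ > 0
say lower-level, higher-volatility subjects go missing more, and about
14% of the between-subject location variance is attributable to the
missingness process. Averaging L = 10 imputations (pooled MSE 0.569)
clearly beats a single stochastic imputation (0.972); both are measured
against the retained pre-masking truth.

`run_study` repeats generate → fit → impute over replicates and reports
per-parameter bias and 95%-interval coverage, per-model-pair mean
imputation error for single and multiple arms, and best/worst difference
ratios; `ppc_pvalue` gives per-subject completed-data posterior
predictive p-values with a WS-variance discrepancy, and `elpd_compare`
ranks models by PSIS-LOO expected log predictive density.

See `docs/methods.md` for model details, priors, the synthetic-data
generator, and numerical choices.

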