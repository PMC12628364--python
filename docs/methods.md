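# Methods

`melsimpute` implements two-step Bayesian multiple imputation for
intensive-longitudinal (EMA) outcomes using three nested mixed models,
together with the synthetic-data generator, simulation-study driver and
imputation diagnostics used to evaluate them. This note records the
models, the numerical choices, and what the shipped defaults do and do
not exercise.

## Models

For subject *i* = 1..N and occasion *j* = 1..n_i, with covariate vector
x_ij and outcome y_ij:

**RILM (random-intercept linear mixed model).**
y_ij | v0_i ~ N(β0 + x_ij'β + v0_i, σ_ε²), with σ_ε² = exp(α0) constant
and v0_i ~ N(0, σ_v0²). α0 is carried as a log-variance so all three
models share one within-subject (WS) variance interface.

**MELS (mixed-effects location-scale model).** The WS variance becomes
log-linear in covariates and a random scale effect:
σ²_ε,ij = exp(α0 + x_ij'α + v1_i), with (v0_i, v1_i) bivariate normal
(SDs σ_v0, σ_v1, correlation ρ_v0v1).

**SPMELS (shared-parameter MELS).** A random-intercept logistic model for
the missingness indicator m_ij (1 = outcome missing at a scheduled
occasion): m_ij ~ Bernoulli(logit⁻¹(τ0 + t_ij'τ + λ_i)). The random
missing effect λ_i ~ N(0, σ_λ²) loads on the outcome's location and
scale through

    v0_i = γ λ_i + η0_i,      v1_i = δ λ_i + η1_i,

with (η0, η1) bivariate normal independent of λ. γ < 0 means subjects
with lower outcome levels respond less; δ > 0 means more erratic
subjects respond less. The share of the location-effect variance
attributable to missingness is (γσ_λ)² / ((γσ_λ)² + σ_η0²), and
analogously for the scale effect — `variance_share`.

**Two-step imputation.** Step 1 draws θ (and the subject effects) from
P(θ | y_obs); Step 2 draws each missing y_ij from its conditional normal
given that draw. Repeating L times gives L completed datasets
(`ImputationSet`); the pooled value at a missing cell is the cellwise
mean (`pool_mean`). L = 1 is the single-imputation arm; the multiple
arm defaults to L = 10. When two variables are missing together
(`x1` and `y` in the simulated design), `sequential_impute` imputes the
covariate first and the outcome second, pairing the draws by copy index.

## Estimation

MELS and SPMELS are fitted by MCMC on the joint of parameters and
subject effects; marginal maximum likelihood would require the
multi-dimensional integrals the location-scale structure makes
expensive. The sampler is an in-package no-U-turn sampler (recursive
tree doubling with a slice variable, dual-averaged step size, diagonal
mass matrix adapted over Stan-style doubling windows) running on
hand-derived analytic gradients. Parameterization: log SDs with
half-normal(3) priors on the SD scale, correlations as tanh of an
unconstrained scalar with a uniform(−1, 1) prior, normal(0, 5) priors on
all regression/loading coefficients (all widths configurable through
`PriorConfig`), and non-centered subject effects, which removes the
funnel between the effect SDs and the effects. Inside the sampler only,
the WS log-variance predictor is clipped to ±30 (gradient zeroed where
clipped) so warmup excursions cannot overflow; the public density
functions are exact. Gradients are verified against central finite
differences in the test suite, and the sampler against closed-form
Gaussian posteriors.

Defaults are 4 chains × (1000 warmup + 1000 retained), target
acceptance 0.8, maximum tree depth 10, and a split-R̂ convergence
threshold of 1.05; every fit reports split-R̂ and effective sample sizes
(via arviz) and a `converged` flag. Reduced-scale runs in the tests use
one chain of 250–400 retained draws with a correspondingly looser
threshold (1.1–1.3), chosen as the smallest chains for which the checks
below are stable.

RILM is fitted by maximum likelihood: the random intercept integrates
out analytically (compound-symmetry marginal, Woodbury form), the
likelihood is maximized on the unconstrained scale (β, α0, log σ_v0),
and the observed-information covariance on that scale defines an
asymptotic-normal Step-1 surrogate that preserves positivity. Subject
intercepts are drawn per Step-1 draw from their empirical-Bayes
conditional normals. With diffuse priors the ML and MCMC routes agree
(tested); an independent cross-check against statsmodels' MixedLM is in
the suite. A σ_v0 estimate at the zero boundary is flagged, not hidden.

Step-1 draws for imputation are taken by stratified thinning (evenly
spaced indices over the concatenated chains) so the L draws are
approximately independent; the ML surrogate draws fresh normals.

Subjects with no observed outcome still receive effect draws: as latent
quantities in the MCMC fits (for SPMELS, informed by their missingness
pattern through λ), or from the random-effects prior given θ in the ML
surrogate.

## Synthetic-data generator

`Scenario.base()` encodes the reference design: 20 subjects × 5 days ×
6 beeps (600 scheduled occasions), a ~20% missing target, and a
four-step shared-parameter generative process — baseline covariate
x2_i ~ N(μ_x2, σ_x2²); λ_i and m_ij from the logistic model with a day
trend and first/last-beep effects; time-varying x1_ij from an SPMELS
block given x2 and λ; outcome y_ij from a second block given x1, x2 and
λ. Missingness masks x1 and y together (non-response hides the whole
report); `true_x1`/`true_y` retain pre-masking values for error
computation. Generation is bit-reproducible given (scenario, seed).

The missingness intercept τ0 is calibrated per scenario, not per
replicate: the expected missing fraction — averaged over the day/beep
design and over λ by Gauss–Hermite quadrature (60 nodes) — is a strictly
increasing function of τ0, and Brent root-finding sets it to the target
exactly. This makes τ0 a well-defined constant of the scenario and the
replicate-to-replicate missing rate binomially variable around the
target (verified by Monte Carlo).

Unvaried true-parameter defaults are the package's choice of realistic
EMA magnitudes: unit-scale effects and covariates (μ_x2 = 0,
σ_x2 = 1), moderate covariate effects on the mean (β = 0.5) and on the
log WS variance (α = 0.2), day trend τ1 = 0.2 with stronger first/last
beep effects τ2 = τ3 = 0.5, σ_λ = 1, residual effect SDs
(σ_η0, σ_η1) = (1, 0.5), and the base condition γ = −0.5, δ = 0.5,
α0 = 0, ρ_η0η1 = −0.2. Grid variants (larger α0, stronger ρ, γ, δ) are
produced by field overrides of `Scenario.base`. Scenarios serialize to
YAML/JSON.

What the generator emulates: informative, subject-heterogeneous
missingness tied to both the level and the volatility of the outcome,
with day/beep structure. What it does not: missingness in time-constant
covariates, residual autocorrelation, random slopes, non-normal
outcomes. Passing tests therefore demonstrate correctness of the method
under its own assumptions, not robustness to those violations.

## Simulation study and metrics

`run_study` repeats generate → fit → impute K times. Per replicate, the
three models are fitted to the outcome with the generating covariates
(x1, x2) for bias and 95%-interval coverage of the generating
parameters (strict-inequality coverage; Wald intervals for ML, quantile
intervals for MCMC); the imputation stage fits the configured x1-models
(covariates x2, day, beep1, beep6) and y-models (plus completed x1) and
records the mean squared imputation error — masked-cell squared error
divided by the total scheduled-cell count — for the single (L = 1) and
pooled multiple (L = 10) arms. The difference ratio between y-models is
100·(worst − best)/worst, ties broken in the fixed order RILM, MELS,
SPMELS. Per-replicate seeds derive from the master seed, so results are
independent of execution order. A fit missing its convergence threshold
is retried once with a derived seed and otherwise excluded with a
logged count.

Two refit policies for the sequential y-stage are provided: `proper`
refits the y-model on each completed-x1 copy (one Step-1 draw per
refit), `fast` fits once on copy 1 and reuses its L Step-1 draws across
copies. Proper is the default; the reduced-scale study in the tests
uses fast, one chain of 300 retained draws, K = 20, and the
shared-parameter model for the x1 stage — the smallest configuration at which the
qualitative orderings (RILM's α0 coverage collapse; multiple < single
error for every model; MELS/SPMELS < RILM pooled error) are stable.
Full-grid runs at K = 100 with long chains are hours-scale and meant
for offline use via the `study` CLI.

## Diagnostics

**Completed-data posterior predictive check.** For each of L_ppc
posterior draws the missing outcomes are imputed, a full replicate of
the schedule is simulated at the same draw with *fresh* subject effects
(the replicate distribution integrates over the fitted hierarchy), and
the per-subject WS variance of replicate and completed series are
compared. p_com is the per-subject proportion of draws with replicate
discrepancy ≥ completed discrepancy; ties count toward the ≥ event.
Values near 0 or 1 indicate misfit; under the generating model the
pooled p_com mean is ~0.5 (tested). Subjects with fewer than two
scheduled occasions are excluded with a log message. For MCMC fits the
L_ppc draws are resampled with replacement from the retained draws;
the ML surrogate draws L_ppc fresh parameter vectors.

**ELPD comparison.** Pointwise log predictive densities conditional on
the subject-effect draws (the convention for hierarchical LOO) feed
PSIS-LOO via arviz; `elpd_compare` reports per-model totals, pairwise
differences with SEs, and flags Pareto-k failures per point. Marginal
(integrated-over-effects) ELPD is out of scope.

## Numerical choices and degenerate inputs

- Expected-rate calibration solves to |rate − target| < 1e-10; the
  bracket always exists because the rate is strictly monotone in τ0.
- `variance_share` errors when both components are zero (undefined);
  boundary σ_resid = 0 returns 1.
- `ws_variance` raises on covariate-length mismatch; correlations are
  validated strictly inside (−1, 1), SDs strictly positive.
- The difference ratio errors when every model's error is zero.
- Datasets must have ≥ 2 subjects with observed outcomes; x2 must be
  constant within subject (hard error); m must be 0/1 on all scheduled
  rows for SPMELS.
- CSV I/O accepts empty fields and "NA" as missing and writes empty
  fields; subject/day/beep indices are 1-based in files.

## Known limitations

- The NUTS engine is single-threaded pure NumPy; it is tuned for the
  sizes here (hundreds of subjects, thousands of rows), not for very
  large N.
- Tensor quadrature cross-checks of the three-dimensional SPMELS
  marginal require a moderate scale-effect SD; very large σ_η1 creates
  a near-singular ridge that the tests avoid (the analytic-reduction
  oracle in the suite handles it).
- Short single chains at N = 20 occasionally miss even the loosened
  R̂ threshold; the study driver's retry-then-exclude policy logs these
  rather than silently absorbing them.
- Rubin's-rules pooling of downstream estimates is provided
  (`rubin_pool`) but is intentionally not the error metric of the
  simulation study, which pools imputed values cellwise; both
  interpretations of "pooling" exist in practice and only the cellwise
  mean enters the reported errors.
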