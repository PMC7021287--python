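# Methods

This note records the statistical model the package implements, the
numerical choices behind the implementation, what the synthetic scenarios
do and do not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Model

The response y_i, i = 1..n, is conditionally independent with parametric
density p(y_i | θ_i1, …, θ_iK). Each distribution parameter is linked to a
structured additive predictor

    g_k(θ_ik) = η_ik = x_i' β^k + Σ_j f_j^k(x_ij) + b_{g(i)}^k,

where g_k maps the parameter's admissible domain to the real line
(identity, log, or logit), f_j are P-splines, and b_g are cluster
intercepts. Families shipped:

| family | parameters | links | support | notes |
|---|---|---|---|---|
| Normal | μ, σ | identity, log | ℝ | σ > 0 |
| LogNormal | μ = E ln Y, σ = SD ln Y | identity, log | (0, ∞) | μ may be negative, hence identity link by default; a log link can be set per model |
| SinghMaddala | μ, σ, τ | log, log, log | (0, ∞) | F(y) = 1 − [1+(y/μ)^σ]^(−τ); E[Y^r] exists iff −σ < r < στ |
| Bernoulli | p | logit | {0,1} | treatment-assignment models only |

The Singh–Maddala parameterization was fixed to the form above (several
orderings circulate); it is numerically identical to
`scipy.stats.burr12(c=σ, d=τ, scale=μ)`, which backs the cdf/quantile/
sampler while the log-density and its parameter gradients are hand-coded
for fitting speed. Closed forms used: mean μ·Γ(1+1/σ)Γ(τ−1/σ)/Γ(τ),
Gini 1 − Γ(τ)Γ(2τ−1/σ)/[Γ(τ−1/σ)Γ(2τ)] (requires στ > 1); log-normal
Gini 2Φ(σ/√2) − 1, Atkinson(1) = 1 − exp(−σ²/2), Theil σ²/2. Where no
closed form exists, expectations are computed by adaptive quadrature on
the quantile scale, ∫₀¹ g(Q(p)) dp (absolute tolerance 1e-9), which is
far better behaved than integrating over an unbounded support when the
right tail is heavy. The Gini uses the single-integral Lorenz form
(1/μ)∫₀¹ Q(p)(2p−1) dp; the literal double integral over |y − z| is kept
in the test suite as an independent oracle.

Atkinson and Theil follow the standard definitions — A_1 = 1 −
exp(E ln Y)/E Y, A_e = 1 − (E Y^{1−e})^{1/(1−e)}/E Y, T = E[(Y/μ) ln(Y/μ)]
— since several normalizations exist in the literature; any alternative
convention can be compared against these formulas directly.

## Estimation

All coefficients of all K predictors are estimated jointly by maximizing
the penalized log-likelihood

    ℓ_p(β) = Σ_i log p(y_i | θ_i(β)) − ½ Σ_b λ_b β_b' S_b β_b,

with S_b a second-difference P-spline penalty (order configurable) or an
identity ridge for cluster intercepts (the penalized-likelihood form of a
Gaussian random intercept; precision fixed by the user, default 1).
Rather than literal backfitting, the package uses L-BFGS with analytic
gradients (chain rule through the inverse links) followed by damped-Newton
polishing with a central finite-difference Hessian, so the reported
optimum satisfies a gradient criterion of max(10⁻⁶, 10⁻⁶·(1+|ℓ_p|)); a
fit that misses it is flagged and warned about, never returned silently.
Internally the design columns of unpenalized terms are centered (when an
intercept is present) and scaled to unit standard deviation; the
reparameterization is undone through its Jacobian, so reported
coefficients, covariance, and effective degrees of freedom refer to the
original scale. This is what makes n ≈ 1000 fits with ~30 coefficients
take ~0.1 s and keeps bootstrap refits (warm-started at the original
estimates) at a few milliseconds.

Start values are deterministic method-of-moments fits of the marginal
outcome mapped into the intercepts (two variants ship; they reach the same
log-likelihood to 1e-6 on the test fixtures). Convergence tolerance 1e-6
and the 500-iteration cap are package defaults. The observed-information
covariance is the inverse penalized Hessian; effective degrees of freedom
are tr[(H+S)⁻¹H], which equals the coefficient count exactly for
unpenalized models and decreases monotonically in the penalty weight.
Smoothing weights λ are fixed per term (`lam=` in the formula); a grid
search over AIC can be scripted with `information_criteria`, no automatic
REML-type selection is attempted. Rows with missing values in the outcome
are dropped with a log note; missing values in covariates are an error
that names the offending rows. Spline bases are cubic B-splines on
equally spaced knots spanning the training range; when the predictor also
contains an intercept the basis is projected onto the null space of its
column means (a sum-to-zero constraint) so the smooth is identifiable,
and prediction clamps to the training range.

## Diagnostics

Normalized quantile residuals r_i = Φ⁻¹(F(y_i; θ̂_i)) are standard normal
under a correctly specified model; for the Bernoulli family they are
randomized uniformly within the cdf jump (seeded). CDF values are clamped
to [1e-12, 1−1e-12] before the probit transform and the clamp count is
reported. The adequacy summary reports mean, variance (ddof 1), moment
skewness, *raw* kurtosis (target 3, never excess), and the Filliben
correlation between sorted residuals and normal order-statistic medians
with plotting positions m₁ = 1 − 0.5^{1/n}, m_n = 0.5^{1/n}, m_i =
(i − 0.3175)/(n + 0.365) — stated explicitly because other q-q position
conventions exist. The cluster check regresses residuals on cluster
indicators and reports adjusted R² and the overall F-test; a clearly
positive adjusted R² argues for cluster-robust inference or cluster
intercepts.

## Effects

The "average unit" profile fixes continuous covariates at arithmetic
means (computed in sorted order, so row permutations cannot change the
result at floating-point level) and categorical *and binary* covariates
at their modes, ties broken to the smallest level and logged. Marginal
effects toggle the treatment column before design construction, so
interaction terms update automatically. Per-row effect distributions and
two-arm conditional density curves use the same path.

## Bootstrap inference

The parametric bootstrap draws one outcome per row from its fitted
conditional distribution, refits the identical specification
(warm-started), and recomputes the statistic; the pairs cluster bootstrap
resamples G whole clusters with replacement and relabels duplicates so
cluster-intercept terms remain well defined. Covariate means entering
"ME at means" statistics are frozen from the original sample by default
(recomputing them per replicate is a documented alternative: pass a
statistic that recomputes the profile from the replicate data). Replicate
failures (non-convergence, degenerate resamples) are dropped and
reported; more than 20% failures is a hard error. B defaults to 499;
percentile intervals use inclusive linear interpolation (an
order-statistic mode is available) and warn when B is too small for the
requested level. The bootstrap t-statistic uses a standard-normal
reference by default with a Student-t(G−1) option under clustering. Every
replicate draws from its own `SeedSequence` child, so results are
bit-identical given (data, spec, B, seed) and independent of execution
order. The IV bootstrap nests N_d second-stage replicates inside each of
N_b first-stage redraws (N_b = 1 degenerates to a fixed-residual
second-stage bootstrap); the RDD bootstrap refits both side models per
replicate and, in fuzzy designs, both treatment-probability models.

## Design adapters

- **DiD** adds treatment, period, and their interaction to every
  parameter predictor; the per-parameter DiD effect is the interaction
  coefficient.
- **Mundlak** appends cluster means of the chosen covariates plus a
  ridge-penalized cluster intercept. Because the within-deviation part of
  a covariate is orthogonal to all cluster-constant columns, the
  covariate's coefficient equals the within (fixed-effects) estimator
  regardless of the ridge precision — verified to 1e-6 in the tests. By
  default only the location parameter's predictor is augmented; pass
  `params=` to extend the device to other parameters.
- **2SRI** fits mean-only first stages (Normal family, linear or spline
  terms) of each endogenous regressor on exogenous covariates and its
  instruments; residuals (optionally standardized to unit variance, the
  default) enter *all* parameter predictors of the second stage, linearly
  or as f(ξ̂) P-splines. First-stage R² is reported as an
  instrument-strength summary. Focusing the first stage on conditional
  means and putting residual terms in every predictor are the package's
  defaults; both are configurable.
- **RDD** fits side-wise models globally within a window (optionally with
  spline terms) rather than selecting one local-polynomial bandwidth, and
  ships a window-sensitivity table instead; the continuity-of-densities
  assumption is recorded in the result metadata. Fuzzy effects divide the
  side-difference of each functional by the jump in treatment probability
  at the cutoff from side-wise logistic fits (a side with deterministic
  treatment contributes its constant, so full compliance reduces exactly
  to the sharp estimate); jumps below 0.01 are refused.
- **FGLS vulnerability** is a 3-step baseline: OLS of ln y on x, OLS of
  squared residuals on x, then weighted re-estimation of the variance and
  mean equations with the fitted variances as weights, and probabilities
  Φ((ln z − m_i)/s_i). Non-positive fitted variances are clamped to 1e-8
  with a reported count. This is a baseline approximation for comparison
  with the simultaneous distributional fit, not a replication of any
  specific FGLS variant.

## Synthetic scenarios

The RCT generator emulates a village-randomized cash-transfer survey:
villages assigned 1:1, six household covariates (poverty index, land,
head's gender/age/indigenous-language/illiteracy) and two village-level
covariates, outcome Singh–Maddala with default intercepts calibrated so
the control arm has mean ≈ 160 and Gini ≈ 0.31 (μ = 201.8, σ = 2.5,
τ = 2.0) — a qualitative match to a right-skewed consumption
distribution, not a numeric replication of any dataset. Default treatment
coefficients are +0.10 on log μ and −0.05 on log σ; the village random
intercept (sd 0.1 on log μ) induces realistic intra-village correlation.
Covariates are simple parametric stand-ins (Gaussian, exponential,
Bernoulli); real survey features such as sampling weights, item
nonresponse, measurement error, and covariate dependence are *not*
emulated, so passing tests demonstrate correctness of the estimators
under the stated model, not robustness to those complications. True
marginal effects in every `ScenarioTruth` are computed through the same
functionals code applied to the true parameter sets, never from separate
formulas. One caveat worth knowing: with these Singh–Maddala settings a
misspecified log-normal fit shows its failure through excess kurtosis and
a depressed Filliben coefficient while the residual *skew* is negative
(the log-normal misses the lower tail here); with real consumption data
the skew signature is typically positive.

The IV generator draws a latent standard-normal confounder loading on
both the endogenous regressor and the outcome location with weight
`confounder_strength`, and an instrument entering only the first stage.
The RDD generator uses a uniform forcing variable with linear link-scale
baselines and a parameter jump applied through treatment; fuzzy mode
draws treatment from side-specific probabilities. The panel generator
correlates unit effects with the covariate at the requested level.

## Problem sizes in the validation suite

The test suite's simulation studies use n = 5000 fits for parameter
recovery (50 seeds) and residual calibration (200 seeds), n = 2000 for
misspecification detection (100 seeds) and 2SRI bias comparison (100
seeds), and the bootstrap-coverage study runs 300 replications at
n = 500 with B = 199 replicates — a deliberate scale-down from B = 499
that leaves percentile-interval coverage essentially unchanged while
keeping the study's total at roughly sixty thousand model fits. The
acceptance script reports a 60-replication coverage summary at B = 99
for the same reason.

## Known limitations

Smoothing parameters are not selected automatically; spatial effects,
count/zero-inflated/unit-interval/multivariate families, boosting-based
selection, Bayesian estimation, BCa intervals, the score bootstrap, and
MSE-optimal RDD bandwidth selectors are out of scope. The 2SRI second
stage is consistent under the control-function assumptions discussed in
the IV literature; with nonlinear first stages it is an approximation.
Percentile intervals can undercover for strongly biased statistics near
parameter-space boundaries (e.g. Gini effects in tiny samples).
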