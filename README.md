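# distreg — distributional regression for treatment effects beyond the mean

Program evaluations usually report how a treatment shifts the *mean* of an
outcome. Many of the questions that matter — does a cash transfer change
consumption *inequality*? does it lower the *probability* of falling below
a poverty line? — live in other features of the outcome distribution.
`distreg` answers them with one coherent model: a distributional regression
(GAMLSS — generalized additive models for location, scale and shape) in
which **every** parameter of a parametric response distribution gets its own
additive predictor,

```
g_k(θ_ik) = β₀^k + β_T^k T_i + f_1^k(x_1i) + … ,   k = 1, …, K,
```

with link functions g_k, linear/categorical terms, P-splines, and
ridge-penalized cluster intercepts. From one penalized-maximum-likelihood
fit the package derives any functional of the conditional distribution —
mean, variance, quantiles, the Gini coefficient, Atkinson(e) and Theil
indices, and vulnerability F(z | x) (the probability of falling below a
poverty line z) — and the **marginal treatment effect at means**: the
change in a functional when T flips 0 → 1 with other covariates fixed at
their means (modes for categoricals).

The intended users are applied statisticians, economists, and
epidemiologists evaluating interventions on skewed, heteroscedastic
outcomes (consumption, income, biomarkers, costs).

What's included:

- **families** — Normal, log-normal, Singh–Maddala (Burr XII, cdf
  `F(y) = 1 − [1 + (y/μ)^σ]^(−τ)` with log links on all three parameters),
  and Bernoulli for treatment-assignment models; registry addressable by
  the usual short names (`NO`, `LOGNO`, `SM`, `BI`).
- **diagnostics** — normalized (randomized) quantile residuals
  `r_i = Φ⁻¹(F(y_i; θ̂_i))`, standard normal under a correct model; the
  five-statistic adequacy summary (mean, variance, skewness, kurtosis,
  Filliben correlation; ideals 0, 1, 0, 3, 1) and a cluster-heterogeneity
  check.
- **inference** — parametric bootstrap, nonparametric pairs cluster
  bootstrap (resampling whole clusters), percentile confidence intervals,
  bootstrap t-tests with the cluster-robust finite-sample factor
  `c = [G/(G−1)]·[(N−1)/(N−K)]`, and convergence traces; nested bootstrap
  wrappers for the IV and RDD designs.
- **designs** — difference-in-differences augmentation, the Mundlak device
  for panels (recovers the within/fixed-effects slope), two-stage residual
  inclusion (2SRI) for endogenous regressors, sharp and fuzzy regression
  discontinuity with window-sensitivity tables, and a 3-step FGLS
  log-normal vulnerability baseline.
- **synthetic** — seeded scenario generators (village-randomized trial,
  IV with a latent confounder, RDD, correlated panel) that return the
  drawn table *and* the ground truth for every supported functional.

## A worked example

```python
import distreg as dr

# a village-randomized trial: 40 villages, Singh-Maddala consumption
df, truth = dr.generate_rct(n_villages=40, households_per_village=30,
                            village_sd=0.0, seed=2)

spec = dr.ModelSpec(outcome="y", family="SM",
                    formulas={"mu": "1 + treat + povindex + land",
                              "sigma": "1 + treat", "tau": "1 + treat"})
fit = dr.fit(spec, df)
print(dr.residual_summary(dr.quantile_residuals(fit, df)))

profile = dr.profile_at_means(df, spec, exclude=("treat",))
for fl in ("mean", "gini"):
    print(fl, dr.marginal_effect(fit, profile, "treat", fl))
```

prints (`examples/02_treatment_effects.py` shows the full table):

```
functional              estimate     truth
mean                     16.8509   18.7673
gini                      0.0077    0.0143
vulnerability:z=94.23    -0.0249       nan
```

Read: for an average household the treatment raises expected consumption
by ≈ 16.9 units, leaves conditional inequality essentially unchanged
(Gini +0.008), and lowers the probability of falling below 60% of the
median consumption by ≈ 2.5 percentage points. The `truth` column is the
generator's known effect, so you can see the estimation error directly.
Attach uncertainty with `dr.pairs_cluster_bootstrap` (see
`examples/03_bootstrap_inference.py`), which resamples whole villages and
reports 95% percentile intervals.

Each script in `examples/` demonstrates one capability end to end:
fit + diagnosis, effects, cluster bootstrap, 2SRI, sharp/fuzzy RDD, and
Mundlak panels.

## Formula syntax

Per-parameter predictors are strings: `"1 + treat + povindex +
s(age, k=10) + cluster(village)"` — `1` intercept (explicit), bare names
linear (categorical if non-numeric), `C(x)` forced categorical with the
smallest level as reference, `a:b` products, `s(x, k, degree, order, lam)`
P-splines, `cluster(g, prec)` ridge-penalized cluster intercepts. Parsing
is deterministic, terms appear in the design in the order written.

## Command line

A thin CLI wraps the library for scripted runs:
`distreg simulate|fit|diagnose|effects|bootstrap|run|compare`, driven by a
YAML config naming the data file, family, per-parameter formulas, design
block, functional list, and bootstrap settings.

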