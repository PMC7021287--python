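"""Panel data with unit effects correlated with a covariate.

Naive random effects are biased for the within-unit slope when the unit
effects correlate with the covariate.  The Mundlak device — adding unit
means of the covariate plus a ridge-penalized unit intercept — recovers
the fixed-effects (within) slope inside the distributional-regression
likelihood.
"""

import distreg as dr

df, truth = dr.generate_panel(n_units=300, n_periods=4,
                              correlation_with_effects=0.8, seed=7)
spec = dr.ModelSpec(outcome="y", family="NO",
                    formulas={"mu": "1 + x", "sigma": "1"})

naive = dr.fit(spec, df)
aug, spec2 = dr.mundlak_augment(df, spec, "unit", ["x"])
mund = dr.fit(spec2, aug)

# within (fixed-effects) oracle for reference
xd = df["x"] - df.groupby("unit")["x"].transform("mean")
yd = df["y"] - df.groupby("unit")["y"].transform("mean")
beta_within = float((xd * yd).sum() / (xd * xd).sum())


def coef(fit, label):
    return dict(zip(fit.labels["mu"], fit.coef["mu"]))[label]


print(f"true slope                 : {truth.extras['beta1']:+.3f}")
print(f"naive random-effects slope : {coef(naive, 'x'):+.3f}  (biased up)")
print(f"Mundlak slope              : {coef(mund, 'x'):+.3f}")
print(f"within (FE) oracle         : {beta_within:+.3f}  "
      "(Mundlak matches to ~1e-6)")
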