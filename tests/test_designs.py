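"""Design adapters: DiD, Mundlak, 2SRI, RDD, and the FGLS baseline."""

import numpy as np
import pandas as pd
import pytest

import distreg as dr
from distreg.designs import fgls_vulnerability


def _coef(fit_result, param, label):
    return dict(zip(fit_result.labels[param], fit_result.coef[param]))[label]


class TestDiD:
    def test_adds_three_terms_per_parameter(self, normal_data):
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x", "sigma": "1"})
        df = normal_data.assign(period=(normal_data.index % 2).astype(float))
        aug = dr.did_augment(spec, "treat", "period", df)
        for p in ("mu", "sigma"):
            assert len(aug.formulas[p]) == len(
                dr.parse_formula(spec.terms_for(p))) + 3

    def test_rejects_non_binary(self, normal_data):
        spec = dr.ModelSpec(outcome="y")
        df = normal_data.assign(period=np.arange(len(normal_data)) * 1.0)
        with pytest.raises(ValueError, match="binary"):
            dr.did_augment(spec, "treat", "period", df)

    def test_matches_linear_did_oracle(self):
        rng = np.random.default_rng(12)
        n = 1200
        g = (rng.uniform(size=n) < 0.5).astype(float)
        period = (rng.uniform(size=n) < 0.5).astype(float)
        y = 1.0 + 0.5 * g + 0.3 * period + 0.7 * g * period + rng.normal(
            size=n)
        df = pd.DataFrame({"y": y, "g": g, "period": period})
        spec = dr.did_augment(
            dr.ModelSpec(outcome="y", family="NO",
                         formulas={"mu": "1", "sigma": "1"}),
            "g", "period", df)
        res = dr.fit(spec, df)
        X = np.column_stack([np.ones(n), g, period, g * period])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert _coef(res, "mu", "g:period") == pytest.approx(beta[3],
                                                             abs=1e-6)

    def test_zero_interaction_recovered(self):
        rng = np.random.default_rng(4)
        n = 3000
        g = (rng.uniform(size=n) < 0.5).astype(float)
        period = (rng.uniform(size=n) < 0.5).astype(float)
        y = 1.0 + 0.5 * g + 0.3 * period + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "g": g, "period": period})
        spec = dr.did_augment(dr.ModelSpec(outcome="y", family="NO"),
                              "g", "period", df)
        res = dr.fit(spec, df)
        assert abs(_coef(res, "mu", "g:period")) < 0.15


class TestMundlak:
    def test_appended_columns_are_group_means(self):
        df, _ = dr.generate_panel(n_units=30, n_periods=3, seed=1)
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x", "sigma": "1"})
        aug, spec2 = dr.mundlak_augment(df, spec, "unit", ["x"])
        expected = df.groupby("unit")["x"].transform("mean")
        np.testing.assert_allclose(aug["x_bar"], expected)

    def test_within_estimator_equivalence(self):
        df, truth = dr.generate_panel(n_units=120, n_periods=4,
                                      correlation_with_effects=0.7, seed=5)
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x", "sigma": "1"})
        aug, spec2 = dr.mundlak_augment(df, spec, "unit", ["x"])
        res = dr.fit(spec2, aug)
        # within (fixed-effects) oracle: OLS on demeaned data
        xd = df["x"] - df.groupby("unit")["x"].transform("mean")
        yd = df["y"] - df.groupby("unit")["y"].transform("mean")
        beta_within = float((xd * yd).sum() / (xd * xd).sum())
        assert _coef(res, "mu", "x") == pytest.approx(beta_within, abs=1e-6)

    def test_naive_biased_mundlak_not(self):
        df, truth = dr.generate_panel(n_units=300, n_periods=4,
                                      correlation_with_effects=0.8, seed=9)
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x", "sigma": "1"})
        naive = dr.fit(spec, df)
        aug, spec2 = dr.mundlak_augment(df, spec, "unit", ["x"])
        mund = dr.fit(spec2, aug)
        b = truth.extras["beta1"]
        assert abs(_coef(naive, "mu", "x") - b) > 0.1
        assert abs(_coef(mund, "mu", "x") - b) < 0.1

    def test_singleton_clusters_mean_is_identity(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0.1, 0.2, 0.3],
                           "unit": [0, 1, 2]})
        spec = dr.ModelSpec(outcome="y",
                            formulas={"mu": "1 + x", "sigma": "1"})
        aug, _ = dr.mundlak_augment(df, spec, "unit", ["x"])
        np.testing.assert_allclose(aug["x_bar"], df["x"])

    def test_constant_within_cluster_warns(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "x": [1.0, 1.0, 2.0, 2.0],
                           "unit": [0, 0, 1, 1]})
        spec = dr.ModelSpec(outcome="y",
                            formulas={"mu": "1 + x", "sigma": "1"})
        with pytest.warns(UserWarning, match="unidentified"):
            dr.mundlak_augment(df, spec, "unit", ["x"])


class TestTSRI:
    def test_first_stage_geometry_and_standardization(self):
        df, _ = dr.generate_iv(n=500, seed=2)
        iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                       instruments={"x_e": ["w"]})
        first = dr.tsri_first_stage(df, iv)
        xi = first.data["xi_x_e"].to_numpy()
        fitted = first.fits["x_e"].predict_params(df)["mu"].to_numpy()
        assert abs(np.dot(xi, fitted - fitted.mean())) < 1e-6
        assert np.var(xi, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_instrument_requirement(self):
        with pytest.raises(ValueError, match="instrument"):
            dr.IVSpec(endogenous=["x_e"], exogenous=[], instruments={})

    def test_first_stage_r2_matches_design(self):
        df, truth = dr.generate_iv(n=20_000, confounder_strength=1.0,
                                   instrument_strength=1.0, seed=6)
        iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                       instruments={"x_e": ["w"]})
        first = dr.tsri_first_stage(df, iv)
        assert first.strength.loc["x_e", "r2"] == pytest.approx(
            truth.extras["design_first_stage_r2"], abs=0.02)

    def test_bias_reduction_under_endogeneity(self):
        gaps_naive, gaps_tsri = [], []
        for seed in range(10):
            df, truth = dr.generate_iv(n=2000, confounder_strength=1.0,
                                       seed=seed)
            spec = dr.ModelSpec(outcome="y", family="NO",
                                formulas={"mu": "1 + x_e + x_o",
                                          "sigma": "1"})
            naive = dr.fit(spec, df)
            iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                           instruments={"x_e": ["w"]})
            first = dr.tsri_first_stage(df, iv)
            second = dr.tsri_second_stage(spec, first.data,
                                          first.residual_columns)
            b = truth.extras["beta_e"]
            gaps_naive.append(_coef(naive, "mu", "x_e") - b)
            gaps_tsri.append(_coef(second, "mu", "x_e") - b)
        assert abs(np.mean(gaps_tsri)) < 0.25 * abs(np.mean(gaps_naive))

    def test_residual_coefficient_null_without_confounding(self):
        coefs = []
        for seed in range(5):
            df, _ = dr.generate_iv(n=2000, confounder_strength=0.0,
                                   seed=seed)
            spec = dr.ModelSpec(outcome="y", family="NO",
                                formulas={"mu": "1 + x_e + x_o",
                                          "sigma": "1"})
            iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                           instruments={"x_e": ["w"]})
            first = dr.tsri_first_stage(df, iv)
            second = dr.tsri_second_stage(spec, first.data,
                                          first.residual_columns)
            coefs.append(_coef(second, "mu", "xi_x_e"))
        assert abs(np.mean(coefs)) < 0.05

    def test_row_misalignment_detected(self):
        df, _ = dr.generate_iv(n=200, seed=1)
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x_e", "sigma": "1"})
        with pytest.raises(ValueError, match="misaligned"):
            dr.tsri_second_stage(spec, df, ["xi_x_e"])


class TestRDD:
    def test_window_must_contain_cutoff(self):
        with pytest.raises(ValueError, match="window"):
            dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0,
                       window=(0.5, 1.0))

    def test_minimum_side_size(self):
        df, _ = dr.generate_rdd(n=200, seed=3)
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0,
                          window=(-0.05, 0.9), min_side=50)
        with pytest.raises(ValueError, match="left"):
            dr.sharp_rdd(df, spec, ["mean"])

    def test_mean_jump_recovered(self):
        df, truth = dr.generate_rdd(n=4000, jumps={"mu": 0.8}, seed=7)
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0)
        res = dr.sharp_rdd(df, spec, ["mean"])
        assert res.effects["mean"] == pytest.approx(truth.true_me["mean"],
                                                    abs=0.15)

    def test_scale_jump_targets_variance_not_mean(self):
        effs_mean, effs_var = [], []
        for seed in range(6):
            df, truth = dr.generate_rdd(n=4000, jumps={"sigma": 0.5},
                                        seed=seed)
            spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0)
            res = dr.sharp_rdd(df, spec, ["mean", "variance"])
            effs_mean.append(res.effects["mean"])
            effs_var.append(res.effects["variance"])
        assert abs(np.mean(effs_mean)) < 0.1
        assert np.mean(effs_var) == pytest.approx(
            truth.true_me["variance"], rel=0.35)

    def test_fuzzy_equals_sharp_under_full_compliance(self):
        df, _ = dr.generate_rdd(n=1500, jumps={"mu": 0.6},
                                fuzzy_compliance=(0.0, 1.0), seed=11)
        sharp_spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0)
        fuzzy_spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0,
                                fuzzy=True, treatment_var="t")
        sharp = dr.sharp_rdd(df, sharp_spec, ["mean", "variance"])
        fuzzy = dr.fuzzy_rdd(df, fuzzy_spec, ["mean", "variance"])
        assert fuzzy.denominator == 1.0
        for k in sharp.effects:
            assert fuzzy.effects[k] == sharp.effects[k]

    def test_fuzzy_compliance_jump_recovery(self):
        df, truth = dr.generate_rdd(n=8000, jumps={"mu": 0.8},
                                    fuzzy_compliance=(0.2, 0.7), seed=21)
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0, fuzzy=True,
                          treatment_var="t")
        res = dr.fuzzy_rdd(df, spec, ["mean"])
        assert res.denominator == pytest.approx(0.5, abs=0.08)
        assert res.effects["mean"] == pytest.approx(truth.true_me["mean"],
                                                    abs=0.3)

    def test_no_probability_jump_rejected(self):
        # alternating treatment on both sides: probability ~0.5 everywhere
        x = np.linspace(-1.0, 1.0, 1001)
        x = x[x != 0]
        t = np.tile([0.0, 1.0], len(x) // 2)
        y = 1.0 + 0.8 * x + np.random.default_rng(0).normal(size=len(x))
        df = pd.DataFrame({"y": y, "x": x, "t": t})
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0, fuzzy=True,
                          treatment_var="t")
        with pytest.raises(ValueError, match="discontinuously"):
            dr.fuzzy_rdd(df, spec, ["mean"])

    def test_window_sensitivity_table(self):
        df, _ = dr.generate_rdd(n=3000, jumps={"mu": 0.8}, seed=4)
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0)
        tab = dr.rdd_window_sensitivity(df, spec, ["mean"],
                                        half_widths=[0.4, 0.7, 1.0])
        assert len(tab) == 3
        assert tab["mean"].std() < 0.3  # estimates stable across windows


class TestFGLS:
    def test_agrees_with_lognormal_gamlss(self):
        rng = np.random.default_rng(15)
        n = 5000
        x = rng.normal(size=n)
        ly = 4.0 + 0.3 * x + rng.normal(scale=0.5, size=n)
        df = pd.DataFrame({"y": np.exp(ly), "x": x})
        z = dr.poverty_line(df["y"].to_numpy())
        tab, info = fgls_vulnerability(df, ["x"], z, outcome="y")
        res = dr.fit(dr.ModelSpec(outcome="y", family="LOGNO",
                                  formulas={"mu": "1 + x", "sigma": "1"}),
                     df)
        pp = res.predict_params(df)
        gam = dr.get_family("LOGNO").cdf(
            z, {"mu": pp["mu"].to_numpy(), "sigma": pp["sigma"].to_numpy()})
        assert np.max(np.abs(tab["vulnerability"].to_numpy() - gam)) < 0.01

    def test_probabilities_vanish_as_z_to_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": np.exp(rng.normal(size=400)),
                           "x": rng.normal(size=400)})
        tab, _ = fgls_vulnerability(df, ["x"], z=1e-8, outcome="y")
        assert tab["vulnerability"].max() < 1e-6

    def test_threshold_at_fitted_mean_gives_half(self):
        # homoscedastic data with x orthogonal to ln y: fitted mean is the
        # sample mean of ln y; z at exp(mean) -> probability 1/2
        rng = np.random.default_rng(8)
        n = 2000
        ly = rng.normal(size=n)
        ly = ly - ly.mean()
        df = pd.DataFrame({"y": np.exp(ly), "x": np.zeros(n) + rng.normal(
            scale=1e-12, size=n)})
        tab, _ = fgls_vulnerability(df, [], z=1.0, outcome="y")
        assert tab["vulnerability"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_rejects_nonpositive_outcome(self):
        df = pd.DataFrame({"y": [1.0, -2.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            fgls_vulnerability(df, ["x"], z=1.0, outcome="y")
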