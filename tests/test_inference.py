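"""Bootstrap machinery: replicate construction, variance/CI identities,
reproducibility, and clustering behaviour."""

import numpy as np
import pandas as pd
import pytest

import distreg as dr
from distreg.inference import BootstrapError, BootstrapResult


def _result(reps, estimate=None):
    reps = np.asarray(reps, dtype=float)
    return BootstrapResult(
        estimate=float(reps.mean()) if estimate is None else estimate,
        replicates=reps, B=len(reps), n_failed=0)


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(19)
    n = 300
    t = (rng.uniform(size=n) < 0.5).astype(float)
    fam = dr.get_family("SM")
    params = {"mu": 100.0 * np.exp(0.15 * t), "sigma": np.full(n, 2.5),
              "tau": np.full(n, 2.0)}
    df = pd.DataFrame({"y": fam.rvs(n, params, rng), "t": t})
    spec = dr.ModelSpec(outcome="y", family="SM",
                        formulas={"mu": "1 + t", "sigma": "1", "tau": "1"})
    return dr.fit(spec, df), df


class TestVarianceIdentities:
    def test_constant_replicates(self):
        assert dr.bootstrap_variance(_result([1.0, 1.0, 1.0])) == 0.0

    def test_hand_arithmetic(self):
        assert dr.bootstrap_variance(_result([0.0, 2.0])) == pytest.approx(2.0)

    def test_matches_numpy_oracle(self):
        reps = np.random.default_rng(0).normal(size=777)
        assert dr.bootstrap_variance(_result(reps)) == pytest.approx(
            np.var(reps, ddof=1), rel=1e-12)

    def test_cluster_factor_exact(self):
        res = _result([0.0, 2.0])
        v = dr.cluster_robust_variance(res, G=2, N=4, K=2)
        assert v == pytest.approx(3.0 * 2.0)  # c = (2/1)*(3/2) = 3

    def test_cluster_factor_limit(self):
        res = _result([0.0, 2.0])
        v = dr.cluster_robust_variance(res, G=10**6, N=10**6, K=2)
        assert v == pytest.approx(dr.bootstrap_variance(res), rel=1e-4)

    def test_cluster_factor_validation(self):
        res = _result([0.0, 2.0])
        with pytest.raises(ValueError):
            dr.cluster_robust_variance(res, G=1, N=4, K=2)
        with pytest.raises(ValueError):
            dr.cluster_robust_variance(res, G=2, N=2, K=2)


class TestTTest:
    def test_zero_estimate(self):
        t, p = dr.t_test(_result([1.0, -1.0], estimate=0.0), 1.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_nominal_five_percent(self):
        t, p = dr.t_test(_result([0.0, 1.0], estimate=1.959964), 1.0)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_sign_antisymmetry(self):
        a = dr.t_test(_result([0.0], estimate=2.3), 0.7)
        b = dr.t_test(_result([0.0], estimate=-2.3), 0.7)
        assert a[0] == -b[0] and a[1] == pytest.approx(b[1])

    def test_t_reference_and_validation(self):
        res = _result([0.0, 1.0], estimate=2.0)
        _, p_norm = dr.t_test(res, 1.0)
        _, p_t = dr.t_test(res, 1.0, reference="t", df=5)
        assert p_t > p_norm
        with pytest.raises(ValueError):
            dr.t_test(res, 0.0)


class TestPercentileCI:
    def test_degenerate(self):
        lo, hi = dr.percentile_ci(_result([2.0] * 50))
        assert lo == hi == 2.0

    def test_matches_quantile_oracle(self):
        reps = np.random.default_rng(3).normal(size=500)
        lo, hi = dr.percentile_ci(_result(reps), level=0.9)
        assert lo == pytest.approx(np.quantile(reps, 0.05))
        assert hi == pytest.approx(np.quantile(reps, 0.95))

    def test_symmetric_replicates(self):
        reps = np.concatenate([np.linspace(-3, 3, 101)])
        lo, hi = dr.percentile_ci(_result(reps))
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_small_b_warns(self):
        with pytest.warns(UserWarning, match="recommend"):
            dr.percentile_ci(_result(np.arange(10.0)))

    def test_order_statistic_mode(self):
        reps = np.random.default_rng(4).normal(size=199)
        lo, hi = dr.percentile_ci(_result(reps), method="lower")
        assert lo in reps and hi in reps


class TestConvergenceTrace:
    def test_final_point_matches_ci(self):
        reps = np.random.default_rng(5).normal(size=300)
        res = _result(reps)
        trace = dr.convergence_trace(res, grid=[50, 150, 300])
        assert len(trace) == 3
        lo, hi = dr.percentile_ci(res)
        assert trace["lower"].iloc[-1] == pytest.approx(lo)
        assert trace["upper"].iloc[-1] == pytest.approx(hi)

    def test_stabilizes(self):
        reps = np.random.default_rng(6).normal(size=2000)
        trace = dr.convergence_trace(_result(reps), grid=[1000, 1500, 2000])
        assert abs(trace["lower"].iloc[-1] - trace["lower"].iloc[-2]) < 0.1

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            dr.convergence_trace(_result(np.arange(10.0)), grid=[20])


class TestParametricBootstrap:
    def test_constant_statistic(self, small_fit):
        res, df = small_fit
        out = dr.parametric_bootstrap(res, df, lambda f, d: 7.0, B=5, seed=1)
        assert dr.bootstrap_variance(out) == 0.0

    def test_seeded_reproducibility(self, small_fit):
        res, df = small_fit
        stat = lambda f, d: f.coef["mu"][1]
        a = dr.parametric_bootstrap(res, df, stat, B=3, seed=9)
        b = dr.parametric_bootstrap(res, df, stat, B=3, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        c = dr.parametric_bootstrap(res, df, stat, B=3, seed=10)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_vector_statistic(self, small_fit):
        res, df = small_fit
        stat = lambda f, d: np.array([f.coef["mu"][0], f.coef["mu"][1]])
        out = dr.parametric_bootstrap(res, df, stat, B=5, seed=2)
        assert out.replicates.shape == (5, 2)
        lo, hi = dr.percentile_ci(out)
        assert lo.shape == (2,)

    def test_failure_rate_guard(self, small_fit):
        res, df = small_fit
        calls = {"n": 0}

        def flaky(f, d):
            calls["n"] += 1
            if calls["n"] > 1:  # point estimate succeeds, replicates fail
                raise RuntimeError("boom")
            return 0.0

        with pytest.raises(BootstrapError, match="failed"):
            dr.parametric_bootstrap(res, df, flaky, B=5, seed=0)

    def test_replicates_drawn_from_fitted_model(self, small_fit):
        # replicate outcomes stay positive (SM support) and differ from data
        res, df = small_fit
        seen = []
        dr.parametric_bootstrap(
            res, df, lambda f, d: seen.append(d["y"].to_numpy()) or 0.0,
            B=2, seed=3)
        replicate_ys = seen[1:]  # first call evaluates the original sample
        assert len(replicate_ys) == 2
        assert all(np.all(s > 0) for s in replicate_ys)
        assert not any(np.array_equal(s, df["y"].to_numpy())
                       for s in replicate_ys)


class TestPairsClusterBootstrap:
    def test_single_cluster_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": [0, 0]})
        spec = dr.ModelSpec(outcome="y")
        with pytest.raises(ValueError, match="2 clusters"):
            dr.pairs_cluster_bootstrap(spec, df, "g", lambda f, d: 0.0, B=2)

    def test_replicates_are_unions_of_whole_clusters(self, rct_data, sm_spec):
        df, _ = rct_data
        seen = []
        dr.pairs_cluster_bootstrap(
            sm_spec, df, "village",
            lambda f, d: seen.append(d) or 0.0, B=2, seed=4)
        orig_blocks = {
            v: np.sort(g["y"].to_numpy()) for v, g in df.groupby("village")}
        for d in seen:
            assert len(d) == len(df)
            for _, blk in d.groupby("village"):
                ys = np.sort(blk["y"].to_numpy())
                assert any(np.array_equal(ys, ob)
                           for ob in orig_blocks.values())

    def test_cluster_variance_exceeds_naive(self):
        # outcomes correlated within villages: ignoring the clustering
        # understates the variance of the treatment-effect estimate
        df, _ = dr.generate_rct(n_villages=30, households_per_village=20,
                                village_sd=0.4, seed=8)
        spec = dr.ModelSpec(outcome="y", family="SM",
                            formulas={"mu": "1 + treat", "sigma": "1",
                                      "tau": "1"})
        stat = lambda f, d: f.coef["mu"][1]
        cl = dr.pairs_cluster_bootstrap(spec, df, "village", stat, B=60,
                                        seed=1)
        base = dr.fit(spec, df)
        par = dr.parametric_bootstrap(base, df, stat, B=60, seed=1)
        assert dr.bootstrap_variance(cl) > dr.bootstrap_variance(par)


class TestNestedBootstraps:
    def test_iv_bootstrap_counts_and_reproducibility(self):
        df, truth = dr.generate_iv(n=400, seed=3)
        iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                       instruments={"x_e": ["w"]})
        spec = dr.ModelSpec(outcome="y", family="NO",
                            formulas={"mu": "1 + x_e + x_o", "sigma": "1"})
        stat = lambda f, d: [c for lab, c in zip(f.labels["mu"], f.coef["mu"])
                             if lab == "x_e"][0]
        a = dr.iv_bootstrap(iv, spec, df, stat, N_b=3, N_d=4, seed=7)
        assert a.B == 12
        b = dr.iv_bootstrap(iv, spec, df, stat, N_b=3, N_d=4, seed=7)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_iv_bootstrap_widens_with_first_stage_uncertainty(self):
        # propagating first-stage noise cannot shrink the interval
        widths_nested, widths_fixed = [], []
        for seed in range(3):
            df, _ = dr.generate_iv(n=300, instrument_strength=0.4, seed=seed)
            iv = dr.IVSpec(endogenous=["x_e"], exogenous=["x_o"],
                           instruments={"x_e": ["w"]})
            spec = dr.ModelSpec(outcome="y", family="NO",
                                formulas={"mu": "1 + x_e + x_o",
                                          "sigma": "1"})
            stat = lambda f, d: [
                c for lab, c in zip(f.labels["mu"], f.coef["mu"])
                if lab == "x_e"][0]
            nested = dr.iv_bootstrap(iv, spec, df, stat, N_b=8, N_d=10,
                                     seed=seed)
            fixed = dr.iv_bootstrap(iv, spec, df, stat, N_b=1, N_d=80,
                                    seed=seed)
            for res, acc in ((nested, widths_nested), (fixed, widths_fixed)):
                lo, hi = dr.percentile_ci(res, level=0.9)
                acc.append(hi - lo)
        assert np.mean(widths_nested) >= 0.9 * np.mean(widths_fixed)

    def test_rdd_bootstrap_reproducible(self):
        df, _ = dr.generate_rdd(n=600, jumps={"mu": 0.5}, seed=2)
        spec = dr.RDDSpec(outcome="y", forcing="x", cutoff=0.0)
        res = dr.sharp_rdd(df, spec, ["mean"])
        stat = lambda r: r.effects["mean"]
        a = dr.rdd_bootstrap(res, stat, B=4, seed=5)
        b = dr.rdd_bootstrap(res, stat, B=4, seed=5)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        lo, hi = dr.percentile_ci(a, level=0.8)
        assert lo <= res.effects["mean"] + 1.0
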