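"""Normalized (randomized) quantile residuals and model-adequacy summaries.

Under a correctly specified model, r_i = Phi^-1(F(y_i; fitted params_i)) is
standard normal, so the usual adequacy check compares the residuals' mean,
variance, skewness, kurtosis (raw, target 3) and the Filliben correlation
coefficient (correlation between sorted residuals and the normal
order-statistic medians of a q-q plot, target 1) against (0, 1, 0, 3, 1).
For discrete families the residuals are randomized within the cdf jump.

A heuristic cluster-heterogeneity check regresses the residuals on cluster
indicators and reports the adjusted R^2 and overall F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-12  # cdf clamp before Phi^-1


@dataclass
class ResidualSet:
    residuals: np.ndarray
    randomized: bool
    seed: object = None
    n_clamped: int = 0

    def __len__(self):
        return len(self.residuals)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.residuals, dtype=dtype)


def quantile_residuals(fit_result, data: pd.DataFrame, randomize: bool = False,
                       seed: int = None) -> ResidualSet:
    """Normalized quantile residuals r_i = Phi^-1(F(y_i; theta_hat_i))."""
    family = fit_result.family
    y = data[fit_result.spec.outcome].to_numpy(float)
    params = {p: fit_result.predict_params(data)[p].to_numpy()
              for p in family.param_names}
    u = np.asarray(family.cdf(y, params), dtype=float)
    if family.discrete:
        if not randomize:
            randomize = True
        lower = np.asarray(family.cdf(y - 1.0, params), dtype=float)
        rng = np.random.default_rng(seed)
        u = lower + rng.uniform(size=len(y)) * (u - lower)
    elif randomize:
        # continuous cdf values are already uniform; flag ignored
        randomize = False
    clipped = (u < _EPS) | (u > 1.0 - _EPS)
    n_clamped = int(np.sum(clipped))
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} cdf value(s) to [{_EPS}, 1-{_EPS}]")
    u = np.clip(u, _EPS, 1.0 - _EPS)
    return ResidualSet(stats.norm.ppf(u), randomized=randomize, seed=seed,
                       n_clamped=n_clamped)


def _values(residuals):
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 1:
        raise ValueError("residuals must be a 1-d array")
    return r


def filliben_positions(n: int) -> np.ndarray:
    """Filliben plotting positions m_1..m_n.

    m_1 = 1 - 0.5^(1/n), m_n = 0.5^(1/n), m_i = (i - 0.3175)/(n + 0.365).
    """
    i = np.arange(1, n + 1, dtype=float)
    m = (i - 0.3175) / (n + 0.365)
    m[0] = 1.0 - 0.5 ** (1.0 / n)
    m[-1] = 0.5 ** (1.0 / n)
    return m


def filliben(residuals) -> float:
    """Correlation between sorted residuals and normal order-statistic medians."""
    r = _values(residuals)
    n = len(r)
    if n < 4:
        raise ValueError("Filliben coefficient needs n >= 4")
    if np.std(r) == 0:
        raise ValueError("zero-variance residuals")
    theo = stats.norm.ppf(filliben_positions(n))
    return float(np.corrcoef(np.sort(r), theo)[0, 1])


def qq_points(residuals) -> pd.DataFrame:
    """Paired (theoretical, sample) quantiles using Filliben positions."""
    r = _values(residuals)
    if len(r) < 2:
        raise ValueError("q-q plot needs n >= 2")
    theo = stats.norm.ppf(filliben_positions(len(r)))
    return pd.DataFrame({"theoretical": theo, "sample": np.sort(r)})


def residual_summary(residuals) -> pd.Series:
    """Mean, variance, skewness, kurtosis (raw, not excess) and Filliben.

    Ideal values under a correct model are 0, 1, 0, 3 and 1.
    """
    r = _values(residuals)
    if len(r) < 4:
        raise ValueError("residual summary needs n >= 4")
    m = r.mean()
    c = r - m
    m2 = np.mean(c**2)
    skew = np.mean(c**3) / m2**1.5
    kurt = np.mean(c**4) / m2**2
    return pd.Series({
        "mean": m,
        "variance": float(np.var(r, ddof=1)),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "filliben": filliben(r),
    })


def cluster_residual_check(residuals, cluster_ids) -> pd.Series:
    """Regress residuals on cluster indicators; adjusted R^2 and overall F-test.

    A sizeable adjusted R^2 (and small F p-value) signals unmodeled
    cluster heterogeneity, suggesting cluster-robust inference or cluster
    random intercepts.
    """
    r = _values(residuals)
    g = np.asarray(cluster_ids)
    if len(g) != len(r):
        raise ValueError("residuals and cluster ids differ in length")
    levels, idx = np.unique(g, return_inverse=True)
    G, n = len(levels), len(r)
    if G < 2:
        raise ValueError("need at least 2 clusters")
    if G >= n:
        raise ValueError("every observation is its own cluster")
    # fitted values of OLS on cluster dummies are the cluster means
    means = np.bincount(idx, weights=r) / np.bincount(idx)
    fitted = means[idx]
    sst = np.sum((r - r.mean())**2)
    sse = np.sum((r - fitted)**2)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - G)
    df1, df2 = G - 1, n - G
    if sse == 0:
        f, p = np.inf, 0.0
    else:
        f = (r2 / df1) / ((1.0 - r2) / df2)
        p = float(stats.f.sf(f, df1, df2))
    return pd.Series({"adj_r2": float(adj), "f_stat": float(f), "p_value": p,
                      "n_clusters": G})
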