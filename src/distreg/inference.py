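"""Bootstrap inference for distributional treatment-effect estimates.

Implements the parametric bootstrap (draw one outcome per row from its
fitted conditional distribution, refit, recompute the statistic), the
nonparametric pairs cluster bootstrap (resample whole clusters with
replacement), nested bootstrap wrappers for two-stage IV and RDD fits, and
the summaries built on the replicates: bootstrap variance

    V_boot = 1/(B-1) * sum_b (theta_b - theta_bar)^2,

its cluster-robust finite-sample modification with factor
c = [G/(G-1)] * [(N-1)/(N-K)], t-tests, percentile confidence intervals,
and a convergence trace of the interval bounds over growing B.

Reproducibility: every replicate draws from its own child stream of a
single SeedSequence, so results are bit-identical for a given seed and
independent of execution order or worker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConvergenceWarning, FitOptions, fit

DEFAULT_B = 499  # replicate count used throughout unless overridden

_MAX_FAILURE_FRACTION = 0.2


class BootstrapError(RuntimeError):
    pass


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class BootstrapResult:
    estimate: object           # scalar or 1-d array from the original sample
    replicates: np.ndarray     # (B_success,) or (B_success, m)
    B: int                     # successful replicates
    n_failed: int
    failures: list = field(default_factory=list)
    method: str = "parametric"
    seed: object = None
    statistic_names: list = None

    @property
    def mean(self):
        return self.replicates.mean(axis=0)


def _finish(estimate, reps, fails, B_requested, method, seed, names=None):
    n_failed = len(fails)
    if n_failed > _MAX_FAILURE_FRACTION * B_requested:
        raise BootstrapError(
            f"{n_failed}/{B_requested} bootstrap replicates failed; "
            f"first failures: {fails[:3]}"
        )
    return BootstrapResult(
        estimate=estimate, replicates=np.asarray(reps, dtype=float),
        B=len(reps), n_failed=n_failed, failures=fails, method=method,
        seed=seed, statistic_names=names,
    )


def _try_statistic(statistic, fit_result, data, fails, reps, tag):
    try:
        if not fit_result.converged:
            raise RuntimeError("replicate fit did not converge")
        reps.append(np.asarray(statistic(fit_result, data), dtype=float))
    except Exception as exc:  # noqa: BLE001 - failures recorded per contract
        fails.append(f"{tag}: {exc}")


def parametric_bootstrap(fit_result, data: pd.DataFrame, statistic,
                         B: int = DEFAULT_B, seed: int = None) -> BootstrapResult:
    """Parametric bootstrap: resample each row's outcome from its fitted
    distribution, refit the same specification, and recompute ``statistic``.

    ``statistic`` is a callable ``(fit_result, data) -> float or 1-d array``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    spec, family = fit_result.spec, fit_result.family
    n = len(data)
    params = {p: fit_result.predict_params(data)[p].to_numpy()
              for p in family.param_names}
    estimate = np.asarray(statistic(fit_result, data), dtype=float)
    warm = fit_result.coef_flat
    children = _seedseq(seed).spawn(B)
    reps, fails = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for b in range(B):
            rng = np.random.default_rng(children[b])
            ystar = family.rvs(n, params, rng)
            dstar = data.copy()
            dstar[spec.outcome] = ystar
            try:
                fstar = fit(spec, dstar, FitOptions(start=warm))
            except Exception as exc:  # noqa: BLE001
                fails.append(f"replicate {b}: {exc}")
                continue
            _try_statistic(statistic, fstar, dstar, fails, reps, f"replicate {b}")
    return _finish(estimate, reps, fails, B, "parametric", seed)


def pairs_cluster_bootstrap(spec, data: pd.DataFrame, cluster_var: str,
                            statistic, B: int = DEFAULT_B,
                            seed: int = None) -> BootstrapResult:
    """Nonparametric pairs cluster bootstrap: resample G whole clusters with
    replacement and refit.  Duplicate resampled clusters receive distinct ids
    so cluster-intercept terms stay well defined.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    groups = data.groupby(cluster_var, sort=True)
    keys = list(groups.groups)
    G = len(keys)
    if G < 2:
        raise ValueError("pairs cluster bootstrap needs at least 2 clusters")
    blocks = {k: groups.get_group(k) for k in keys}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        base_fit = fit(spec, data)
        estimate = np.asarray(statistic(base_fit, data), dtype=float)
        warm = base_fit.coef_flat
        children = _seedseq(seed).spawn(B)
        reps, fails = [], []
        for b in range(B):
            rng = np.random.default_rng(children[b])
            draw = rng.integers(0, G, size=G)
            parts = []
            for new_id, gi in enumerate(draw):
                blk = blocks[keys[gi]].copy()
                blk[cluster_var] = new_id
                parts.append(blk)
            dstar = pd.concat(parts, ignore_index=True)
            if dstar[cluster_var].nunique() < 2 and _has_cluster_terms(spec):
                fails.append(f"replicate {b}: single unique cluster")
                continue
            try:
                fstar = fit(spec, dstar, FitOptions(start=warm))
            except Exception as exc:  # noqa: BLE001
                fails.append(f"replicate {b}: {exc}")
                continue
            _try_statistic(statistic, fstar, dstar, fails, reps, f"replicate {b}")
    return _finish(estimate, reps, fails, B, "pairs-cluster", seed)


def _has_cluster_terms(spec):
    from .formula import parse_formula
    for p in spec.resolved_family().param_names:
        terms = spec.terms_for(p)
        if isinstance(terms, str):
            terms = parse_formula(terms)
        if any(t.kind == "cluster" for t in terms):
            return True
    return False


def bootstrap_variance(result: BootstrapResult):
    """Sample variance of the replicate statistics (1/(B-1) convention)."""
    if result.B < 2:
        raise ValueError("need at least 2 successful replicates")
    return result.replicates.var(axis=0, ddof=1)


def cluster_robust_variance(result: BootstrapResult, G: int, N: int, K: int):
    """Cluster-robust bootstrap variance: c * V_boot with
    c = [G/(G-1)] * [(N-1)/(N-K)]."""
    if G < 2:
        raise ValueError("need G >= 2 clusters")
    if N <= K:
        raise ValueError("need N > K (observations > estimated quantities)")
    c = (G / (G - 1.0)) * ((N - 1.0) / (N - K))
    return c * bootstrap_variance(result)


def t_test(result: BootstrapResult, variance, reference: str = "normal",
           df: int = None):
    """t = estimate / sqrt(variance) with a two-sided p-value.

    The reference distribution is standard normal by default; pass
    ``reference="t"`` with ``df`` (e.g. G-1 under clustering) to use a
    Student t reference.
    """
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be positive")
    t = np.asarray(result.estimate, dtype=float) / np.sqrt(variance)
    if reference == "t":
        if not df or df < 1:
            raise ValueError("t reference needs df >= 1")
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    if np.ndim(t) == 0:
        return float(t), float(p)
    return t, p


def percentile_ci(result: BootstrapResult, level: float = 0.95,
                  method: str = "linear"):
    """Equal-tailed percentile interval from the replicate statistics.

    ``method`` is the quantile interpolation rule: "linear" (inclusive
    linear interpolation, default) or "lower"/"higher" order-statistic
    modes.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    min_b = int(np.ceil(2.0 / (1.0 - level)))
    if result.B < min_b:
        warnings.warn(
            f"only B={result.B} replicates for a {level:.0%} interval; "
            f"recommend B >= {min_b}"
        )
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(result.replicates, alpha, axis=0, method=method)
    hi = np.quantile(result.replicates, 1.0 - alpha, axis=0, method=method)
    if np.ndim(lo) == 0:
        return float(lo), float(hi)
    return lo, hi


def convergence_trace(result: BootstrapResult, grid=None,
                      level: float = 0.95) -> pd.DataFrame:
    """Percentile-interval bounds using only the first B' replicates,
    for each B' in ``grid`` — a diagnostic for whether B was large enough."""
    if grid is None:
        grid = np.unique(np.linspace(20, result.B, 25, dtype=int))
    grid = np.asarray(grid, dtype=int)
    if np.any(grid > result.B):
        raise ValueError("grid entries must not exceed B")
    rows = []
    alpha = (1.0 - level) / 2.0
    for bp in grid:
        sub = result.replicates[:bp]
        rows.append({
            "B": int(bp),
            "lower": float(np.quantile(sub, alpha)),
            "upper": float(np.quantile(sub, 1.0 - alpha)),
        })
    return pd.DataFrame(rows)


def iv_bootstrap(iv_spec, second_stage_spec, data: pd.DataFrame, statistic,
                 N_b: int = 20, N_d: int = 25, seed: int = None,
                 flexible: bool = False) -> BootstrapResult:
    """Nested bootstrap for two-stage residual inclusion.

    Outer loop (N_b): parametric bootstrap of the first-stage mean models —
    endogenous regressors are redrawn from their fitted first-stage
    distributions, the first stages are refitted, and the control-function
    residuals recomputed against the *original* endogenous values.  Inner
    loop (N_d): parametric bootstrap of the second-stage distributional
    model given those residuals.  Yields N_b * N_d replicate statistics, so
    first-stage estimation uncertainty propagates into the interval.
    With N_b = 1 the original first-stage residuals are kept fixed and the
    procedure reduces to a plain second-stage parametric bootstrap.
    """
    from .designs import tsri_first_stage, tsri_second_stage

    if N_b < 1 or N_d < 1:
        raise ValueError("N_b and N_d must be >= 1")
    first = tsri_first_stage(data, iv_spec)
    base_fit = tsri_second_stage(second_stage_spec, first.data,
                                 first.residual_columns, flexible=flexible)
    estimate = np.asarray(statistic(base_fit, first.data), dtype=float)
    outer = _seedseq(seed).spawn(N_b)
    reps, fails = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(N_b):
            outer_draw, inner_seed = outer[k].spawn(2)
            rng = np.random.default_rng(outer_draw)
            if N_b == 1:
                fs_k = first
            else:
                try:
                    fs_k = first.parametric_redraw(iv_spec, data, rng)
                except Exception as exc:  # noqa: BLE001
                    fails.append(f"outer {k}: {exc}")
                    continue
            try:
                fit_k = tsri_second_stage(second_stage_spec, fs_k.data,
                                          fs_k.residual_columns,
                                          flexible=flexible)
            except Exception as exc:  # noqa: BLE001
                fails.append(f"outer {k}: {exc}")
                continue
            inner = parametric_bootstrap(
                fit_k, fs_k.data, statistic, B=max(N_d, 2), seed=inner_seed,
            )
            reps.extend(inner.replicates[:N_d])
            fails.extend(f"outer {k} {m}" for m in inner.failures)
    return _finish(estimate, reps, fails, N_b * N_d, "iv-nested", seed)


def rdd_bootstrap(rdd_result, statistic, B: int = DEFAULT_B,
                  seed: int = None) -> BootstrapResult:
    """Parametric bootstrap for regression-discontinuity fits.

    Each replicate redraws outcomes from the fitted side distributions and
    refits both side models (sharp: 2 refits per replicate; fuzzy:
    additionally redraws treatment from the side-wise assignment models and
    refits those, 4 refits per replicate).  ``statistic`` maps a refitted
    RDD result to a scalar (e.g. ``lambda r: r.effects["mean"]``).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    estimate = np.asarray(statistic(rdd_result), dtype=float)
    children = _seedseq(seed).spawn(B)
    reps, fails = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for b in range(B):
            rng = np.random.default_rng(children[b])
            try:
                rep = rdd_result.resample_and_refit(rng)
                reps.append(np.asarray(statistic(rep), dtype=float))
            except Exception as exc:  # noqa: BLE001
                fails.append(f"replicate {b}: {exc}")
    return _finish(estimate, reps, fails, B, "rdd", seed)
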