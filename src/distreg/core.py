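"""Model specification and penalized maximum-likelihood fitting.

A :class:`ModelSpec` names the outcome column, the response family, and one
predictor formula per distribution parameter.  :func:`fit` maximizes the
penalized log-likelihood

    l_p(beta) = sum_i log p(y_i | theta_i(beta)) - 1/2 sum_b w_b beta_b' S_b beta_b

jointly over the coefficients of all distribution parameters with L-BFGS
(analytic gradients via the chain rule through the links) followed by Newton
polishing with a finite-difference Hessian, so the reported optimum satisfies
a tight gradient-norm criterion.  Penalty blocks S_b come from P-spline
difference penalties and ridge-penalized cluster intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.optimize import minimize

from .families import Family, get_family
from .formula import DesignError, ParamDesign, parse_formula
from .links import get_link


class FitError(RuntimeError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelSpec:
    """Outcome + family + one additive predictor per distribution parameter.

    ``formulas`` maps parameter names (e.g. ``mu``, ``sigma``, ``tau``) to
    formula strings or TermSpec lists; omitted parameters default to an
    intercept-only predictor.  ``links`` optionally overrides the family's
    default link per parameter.
    """

    outcome: str
    family: object = "Normal"
    formulas: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)

    def resolved_family(self) -> Family:
        return get_family(self.family)

    def link_for(self, param):
        fam = self.resolved_family()
        return get_link(self.links.get(param, fam.default_links[param]))

    def terms_for(self, param):
        return self.formulas.get(param, "1")

    def with_formulas(self, **updates) -> "ModelSpec":
        new = dict(self.formulas)
        new.update(updates)
        return replace(self, formulas=new)


@dataclass
class FitOptions:
    maxiter: int = 500
    gtol: float = 1e-6
    start: np.ndarray = None
    init_variant: int = 0
    polish: bool = True


@dataclass
class FitResult:
    spec: ModelSpec
    family: Family
    designs: dict          # param -> ParamDesign
    coef: dict             # param -> coefficient vector
    labels: dict           # param -> column labels
    loglik: float          # unpenalized log-likelihood at the optimum
    penalized_loglik: float
    edf: float
    cov: np.ndarray        # covariance of the stacked coefficient vector
    fitted_params: pd.DataFrame
    converged: bool
    n_iter: int
    grad_norm: float
    n_obs: int

    @property
    def coef_flat(self) -> np.ndarray:
        return np.concatenate([self.coef[p] for p in self.family.param_names])

    def coef_table(self) -> pd.DataFrame:
        rows = []
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        pos = 0
        for p in self.family.param_names:
            for lab, b in zip(self.labels[p], self.coef[p]):
                rows.append({"parameter": p, "term": lab,
                             "estimate": b, "se": se[pos]})
                pos += 1
        return pd.DataFrame(rows)

    def predict_params(self, newdata: pd.DataFrame) -> pd.DataFrame:
        return predict_params(self, newdata)

    def information_criteria(self):
        return information_criteria(self)


def _split(beta, designs, param_names):
    out, pos = {}, 0
    for p in param_names:
        k = designs[p].ncol
        out[p] = beta[pos:pos + k]
        pos += k
    return out


def _predictor_params(beta, designs, mats, spec, param_names):
    coefs = _split(beta, designs, param_names)
    etas = {p: mats[p] @ coefs[p] for p in param_names}
    params = {p: spec.link_for(p).inverse(etas[p]) for p in param_names}
    return coefs, etas, params


def fit(spec: ModelSpec, data: pd.DataFrame, options: FitOptions = None) -> FitResult:
    """Fit a distributional regression model by penalized maximum likelihood."""
    options = options or FitOptions()
    family = spec.resolved_family()
    pnames = family.param_names
    if spec.outcome not in data.columns:
        raise DesignError(f"outcome column {spec.outcome!r} not in data")
    if data[spec.outcome].isna().any():
        data = data.dropna(subset=[spec.outcome])
    y = data[spec.outcome].to_numpy(float)
    n = len(y)
    if n == 0:
        raise DesignError("empty data table")
    lo, hi = family.support
    if family.discrete:
        if not np.isin(y, (0.0, 1.0)).all():
            raise DesignError("Bernoulli outcome must be coded 0/1")
    elif np.any(y <= lo) or np.any(y >= hi):
        raise DesignError(
            f"outcome values outside the open support ({lo}, {hi}) "
            f"of family {family.name}"
        )

    designs = {p: ParamDesign(spec.terms_for(p), data) for p in pnames}
    mats = {p: designs[p].matrix(data, training=True) for p in pnames}
    sizes = {p: designs[p].ncol for p in pnames}
    ptotal = sum(sizes.values())
    if n <= ptotal:
        raise FitError(
            f"n={n} must exceed the total coefficient count {ptotal}"
        )
    _check_rank(designs, mats, pnames)

    pen = {p: designs[p].penalty_matrix() for p in pnames}

    # center and scale unpenalized non-constant columns internally (centering
    # only when an intercept can absorb the offset): the optimizer sees a
    # well-conditioned problem while coefficients are reported on the
    # original scale via the Jacobian A with beta_orig = A @ gamma.
    # Penalized blocks are left untouched so penalties apply unchanged.
    trans = []
    for p in pnames:
        X = mats[p]
        k = sizes[p]
        A = np.eye(k)
        penalized = designs[p].penalized_cols
        sd = X.std(axis=0)
        free = np.where((~penalized) & (sd > 0))[0]
        try:
            icol = designs[p].labels.index("(Intercept)")
        except ValueError:
            icol = None
        if len(free):
            s = sd[free]
            m = X[:, free].mean(axis=0) if icol is not None else np.zeros(
                len(free))
            X = X.copy()
            X[:, free] = (X[:, free] - m) / s
            mats[p] = X
            A[free, free] = 1.0 / s
            if icol is not None:
                A[icol, free] = -m / s
        trans.append(A)
    A_flat = _block_diag(trans)

    def unpack(beta):
        return _predictor_params(beta, designs, mats, spec, pnames)

    def neg_penll(beta):
        coefs, _, params = unpack(beta)
        ll = float(np.sum(family.logpdf(y, params)))
        penv = sum(0.5 * coefs[p] @ pen[p] @ coefs[p] for p in pnames)
        if not np.isfinite(ll):
            return np.inf
        return -(ll - penv)

    def grad(beta):
        coefs, etas, params = unpack(beta)
        d = family.dlogpdf(y, params)
        gs = []
        for p in pnames:
            w = d[p] * spec.link_for(p).dinverse(etas[p])
            gs.append(-(mats[p].T @ w) + pen[p] @ coefs[p])
        return np.concatenate(gs)

    beta0 = np.linalg.solve(
        A_flat, _start_values(spec, family, designs, y, options))
    res = minimize(
        neg_penll, beta0, jac=grad, method="L-BFGS-B",
        options={"maxiter": options.maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    beta = res.x
    n_iter = int(res.nit)
    if not np.isfinite(neg_penll(beta)):
        raise FitError("optimizer returned a non-finite objective")

    if options.polish:
        beta, extra = _newton_polish(neg_penll, grad, beta, options.gtol)
        n_iter += extra
    g = grad(beta)
    gnorm = float(np.max(np.abs(g)))
    converged = gnorm <= max(options.gtol, 1e-6 * (1.0 + abs(neg_penll(beta))))
    if not converged:
        warnings.warn(
            f"fit did not reach gradient tolerance (|g|_max={gnorm:.3g})",
            ConvergenceWarning,
        )

    _, _, params = unpack(beta)
    # back to the original coefficient scale (penalized blocks untouched)
    beta_orig = A_flat @ beta
    coefs = _split(beta_orig, designs, pnames)
    ll = float(np.sum(family.logpdf(y, params)))
    penv = sum(0.5 * coefs[p] @ pen[p] @ coefs[p] for p in pnames)
    H = _fd_hessian(grad, beta)           # penalized information (work space)
    S = _block_diag([pen[p] for p in pnames])
    Hun = H - S                           # unpenalized observed information
    edf = _edf(Hun, H, ptotal)            # invariant under the reparameterization
    cov = A_flat @ pinvh(H) @ A_flat.T

    fitted = pd.DataFrame(
        {p: np.broadcast_to(params[p], (n,)).copy() for p in pnames},
        index=data.index,
    )
    return FitResult(
        spec=spec, family=family, designs=designs,
        coef=coefs, labels={p: designs[p].labels for p in pnames},
        loglik=ll, penalized_loglik=ll - penv, edf=edf, cov=cov,
        fitted_params=fitted, converged=bool(converged),
        n_iter=n_iter, grad_norm=gnorm, n_obs=n,
    )


def _check_rank(designs, mats, pnames):
    for p in pnames:
        d = designs[p]
        unpen = ~d.penalized_cols
        if unpen.sum() == 0:
            continue
        X = mats[p][:, unpen]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FitError(
                f"design for parameter {p!r} is rank deficient "
                f"(collinear unpenalized terms among {list(np.array(d.labels)[unpen])})"
            )


def _start_values(spec, family, designs, y, options):
    if options.start is not None:
        return np.asarray(options.start, dtype=float)
    init = family.initial_params(y, variant=options.init_variant)
    parts = []
    for p in family.param_names:
        b = np.zeros(designs[p].ncol)
        for j, t in enumerate(designs[p].terms):
            if t.kind == "intercept":
                pos = sum(bt.ncol for bt in designs[p].built[:j])
                b[pos] = float(spec.link_for(p)(init[p]))
                break
        parts.append(b)
    return np.concatenate(parts)


def _newton_polish(f, grad, beta, gtol, max_steps=50):
    """Damped Newton refinement with a finite-difference Hessian.

    If the Newton step is not a descent direction (indefinite Hessian far
    from the optimum), the Hessian is ridge-damped Levenberg-style until
    the objective improves.
    """
    steps = 0
    eye = np.eye(len(beta))
    for _ in range(max_steps):
        g = grad(beta)
        gnorm = np.max(np.abs(g))
        if gnorm <= gtol:
            break
        H = _fd_hessian(grad, beta)
        scale = max(np.max(np.abs(np.diag(H))), 1.0)
        f0 = f(beta)
        improved = False
        lam = 1e-10
        for _ in range(8):
            try:
                delta = np.linalg.solve(H + lam * scale * eye, g)
            except np.linalg.LinAlgError:
                lam *= 1e4
                continue
            # expected quadratic decrease; below float precision of the
            # objective the remaining gradient is numerical noise
            if 0.5 * abs(g @ delta) < 1e-13 * (1.0 + abs(f0)):
                return beta, steps
            step = 1.0
            for _ in range(12):
                cand = beta - step * delta
                fc = f(cand)
                if np.isfinite(fc) and fc <= f0 - 1e-14 * abs(f0):
                    beta, improved = cand, True
                    break
                step *= 0.5
            if improved:
                break
            lam *= 1e4
        steps += 1
        if not improved:
            break
    return beta, steps


def _fd_hessian(grad, beta, eps=1e-6):
    p = len(beta)
    H = np.empty((p, p))
    for j in range(p):
        h = eps * (1.0 + abs(beta[j]))
        e = np.zeros(p)
        e[j] = h
        H[:, j] = (grad(beta + e) - grad(beta - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _block_diag(blocks):
    sizes = [b.shape[0] for b in blocks]
    out = np.zeros((sum(sizes), sum(sizes)))
    pos = 0
    for b in blocks:
        k = b.shape[0]
        out[pos:pos + k, pos:pos + k] = b
        pos += k
    return out


def _edf(Hun, Hpen, ptotal):
    """Effective degrees of freedom: trace of Hpen^-1 Hun (hat-trace analogue)."""
    try:
        return float(np.trace(np.linalg.solve(Hpen, Hun)))
    except np.linalg.LinAlgError:
        return float(ptotal)


def loglikelihood(spec: ModelSpec, coefficients, data: pd.DataFrame) -> float:
    """Unpenalized log-likelihood at a given coefficient layout.

    ``coefficients`` is either a dict param -> vector or a flat vector in
    parameter order.
    """
    family = spec.resolved_family()
    pnames = family.param_names
    y = data[spec.outcome].to_numpy(float)
    designs = {p: ParamDesign(spec.terms_for(p), data) for p in pnames}
    mats = {p: designs[p].matrix(data, training=True) for p in pnames}
    if isinstance(coefficients, dict):
        flat = []
        for p in pnames:
            b = np.asarray(coefficients[p], dtype=float)
            if b.shape != (designs[p].ncol,):
                raise ValueError(
                    f"coefficient layout mismatch for {p!r}: "
                    f"got {b.shape}, expected ({designs[p].ncol},)"
                )
            flat.append(b)
        beta = np.concatenate(flat)
    else:
        beta = np.asarray(coefficients, dtype=float)
        total = sum(designs[p].ncol for p in pnames)
        if beta.shape != (total,):
            raise ValueError(
                f"coefficient layout mismatch: got {beta.shape}, expected ({total},)"
            )
    _, _, params = _predictor_params(beta, designs, mats, spec, pnames)
    return float(np.sum(family.logpdf(y, params)))


def predict_params(fit_result: FitResult, newdata: pd.DataFrame) -> pd.DataFrame:
    """Per-row fitted distribution parameters at new covariate values."""
    family = fit_result.family
    out = {}
    for p in family.param_names:
        X = fit_result.designs[p].matrix(newdata)
        eta = X @ fit_result.coef[p]
        out[p] = fit_result.spec.link_for(p).inverse(eta)
    return pd.DataFrame(out, index=newdata.index)


def information_criteria(fit_result: FitResult):
    """(AIC, BIC) using effective degrees of freedom."""
    edf, ll, n = fit_result.edf, fit_result.loglik, fit_result.n_obs
    return -2.0 * ll + 2.0 * edf, -2.0 * ll + np.log(n) * edf
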