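"""Evaluation-design adapters around the distributional regression core.

- difference-in-differences: augment every parameter predictor with
  treatment, period, and their interaction;
- Mundlak device for panel/clustered data: add cluster means of the
  time-varying covariates plus a cluster random intercept, so the
  within-cluster (fixed-effects) slope is recovered while keeping the
  random-effects likelihood;
- two-stage residual inclusion (2SRI) for endogenous regressors: mean-model
  first stages on instruments + exogenous covariates, their residuals
  entered as control functions into every parameter predictor of the
  second-stage distributional model;
- sharp and fuzzy regression discontinuity: side-wise distributional models
  within a window around the cutoff, functional differences evaluated at
  the cutoff, scaled in the fuzzy case by the jump in treatment
  probability estimated from side-wise logistic models;
- a 3-step FGLS log-normal vulnerability baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelSpec, fit
from .effects import profile_at_means
from .formula import TermSpec, parse_formula
from .functionals import FunctionalSpec, evaluate


def _term_list(spec: ModelSpec, param) -> list:
    terms = spec.terms_for(param)
    return list(parse_formula(terms)) if isinstance(terms, str) else list(terms)


# --------------------------------------------------------------------------
# difference in differences
# --------------------------------------------------------------------------

def did_augment(spec: ModelSpec, treatment_var: str, period_var: str,
                data: pd.DataFrame = None) -> ModelSpec:
    """Add treatment, period, and treatment x period to every parameter
    predictor; the DiD effect on each parameter is the interaction
    coefficient."""
    if data is not None:
        for v in (treatment_var, period_var):
            vals = set(pd.unique(data[v].dropna()).astype(float))
            if not vals <= {0.0, 1.0}:
                raise ValueError(f"{v!r} must be binary 0/1 for DiD")
    new = {}
    for p in spec.resolved_family().param_names:
        terms = _term_list(spec, p)
        terms += [
            TermSpec("linear", (treatment_var,)),
            TermSpec("linear", (period_var,)),
            TermSpec("interaction", (treatment_var, period_var)),
        ]
        new[p] = terms
    return replace(spec, formulas=new)


# --------------------------------------------------------------------------
# Mundlak device
# --------------------------------------------------------------------------

def mundlak_augment(data: pd.DataFrame, spec: ModelSpec, cluster_var: str,
                    variables, params=None, precision: float = 1.0):
    """Append cluster means of ``variables`` and a cluster random intercept.

    Returns (augmented data, augmented ModelSpec).  By default only the
    first (location) distribution parameter's predictor is augmented; pass
    ``params`` to extend others.  With the cluster means included, the
    coefficients on the original variables estimate within-cluster
    (fixed-effects) slopes.
    """
    if cluster_var not in data.columns:
        raise ValueError(f"cluster column {cluster_var!r} not in data")
    fam = spec.resolved_family()
    params = [fam.param_names[0]] if params is None else list(params)
    out = data.copy()
    mean_cols = []
    for v in variables:
        g = out.groupby(cluster_var)[v]
        if (g.transform("var").fillna(0.0) == 0).all():
            warnings.warn(
                f"{v!r} is constant within every cluster; "
                "its within-effect is unidentified"
            )
        col = f"{v}_bar"
        out[col] = g.transform("mean")
        mean_cols.append(col)
    new = dict(spec.formulas)
    for p in params:
        terms = _term_list(spec, p)
        terms += [TermSpec("linear", (c,)) for c in mean_cols]
        terms.append(TermSpec("cluster", (cluster_var,), precision=precision))
        new[p] = terms
    return out, replace(spec, formulas=new)


# --------------------------------------------------------------------------
# two-stage residual inclusion
# --------------------------------------------------------------------------

@dataclass
class IVSpec:
    """Configuration of a 2SRI setup.

    ``instruments`` maps each endogenous variable to its instrument list
    (every endogenous variable needs at least one).  First stages are mean
    models (Normal family) of the endogenous variable on exogenous
    covariates and instruments, linear by default or with P-spline terms
    when ``residual_treatment='spline'`` requests flexible first stages.
    """

    endogenous: list
    exogenous: list
    instruments: dict
    residual_treatment: str = "linear"   # linear | spline (second-stage f(xi))
    first_stage_spline: bool = False
    standardize: bool = True
    spline_k: int = 8

    def __post_init__(self):
        for e in self.endogenous:
            if not self.instruments.get(e):
                raise ValueError(
                    f"endogenous variable {e!r} needs at least one instrument"
                )


@dataclass
class FirstStageResult:
    data: pd.DataFrame
    residual_columns: list
    fits: dict
    strength: pd.DataFrame  # per endogenous variable: r2, resid_sd
    scales: dict = field(default_factory=dict)

    def parametric_redraw(self, iv_spec: IVSpec, original: pd.DataFrame, rng):
        """One outer IV-bootstrap step: redraw each endogenous variable from
        its fitted first-stage distribution, refit the first stages, and
        recompute residuals against the original endogenous values."""
        star = original.copy()
        for e in iv_spec.endogenous:
            f = self.fits[e]
            mu = f.predict_params(original)["mu"].to_numpy()
            sd = float(self.strength.loc[e, "resid_sd"])
            star[e] = mu + rng.normal(scale=sd, size=len(original))
        redrawn = tsri_first_stage(star, iv_spec)
        # residuals relative to the original endogenous values (xi = x_e - x_hat[k])
        out = original.copy()
        for e, col in zip(iv_spec.endogenous, redrawn.residual_columns):
            xhat = redrawn.fits[e].predict_params(original)["mu"].to_numpy()
            xi = original[e].to_numpy(float) - xhat
            if iv_spec.standardize:
                s = xi.std(ddof=1)
                xi = xi / s if s > 0 else xi
            out[col] = xi
        return FirstStageResult(out, redrawn.residual_columns, redrawn.fits,
                                redrawn.strength)


def tsri_first_stage(data: pd.DataFrame, iv_spec: IVSpec) -> FirstStageResult:
    """First stage of 2SRI: fit the mean model of each endogenous variable
    on exogenous covariates and instruments, store residuals xi_hat."""
    out = data.copy()
    fits, rows, cols, scales = {}, [], [], {}
    for e in iv_spec.endogenous:
        rhs = ["1"]
        for v in iv_spec.exogenous + list(iv_spec.instruments[e]):
            rhs.append(f"s({v}, k={iv_spec.spline_k})"
                       if iv_spec.first_stage_spline else v)
        spec = ModelSpec(outcome=e, family="Normal",
                         formulas={"mu": " + ".join(rhs), "sigma": "1"})
        f = fit(spec, data)
        xhat = f.predict_params(data)["mu"].to_numpy()
        x = data[e].to_numpy(float)
        xi = x - xhat
        r2 = 1.0 - np.sum(xi**2) / np.sum((x - x.mean())**2)
        col = f"xi_{e}"
        scale = xi.std(ddof=1)
        if iv_spec.standardize and scale > 0:
            out[col] = xi / scale
        else:
            out[col] = xi
        fits[e] = f
        scales[e] = scale
        cols.append(col)
        rows.append({"endogenous": e, "r2": r2, "resid_sd": scale})
    strength = pd.DataFrame(rows).set_index("endogenous")
    return FirstStageResult(out, cols, fits, strength, scales)


def tsri_second_stage(spec: ModelSpec, data: pd.DataFrame, residual_columns,
                      flexible: bool = False, params=None,
                      spline_k: int = 8):
    """Second stage of 2SRI: refit the distributional model with the
    first-stage residuals as control-function terms.

    Residual terms enter every distribution parameter's predictor by
    default (``params`` restricts this); ``flexible`` uses P-splines
    f(xi_hat) instead of linear terms.
    """
    for c in residual_columns:
        if c not in data.columns:
            raise ValueError(f"residual column {c!r} missing; rows misaligned?")
    fam = spec.resolved_family()
    params = list(fam.param_names) if params is None else list(params)
    new = dict(spec.formulas)
    for p in params:
        terms = _term_list(spec, p)
        for c in residual_columns:
            terms.append(
                TermSpec("spline", (c,), k=spline_k) if flexible
                else TermSpec("linear", (c,))
            )
        new[p] = terms
    return fit(replace(spec, formulas=new), data)


# --------------------------------------------------------------------------
# regression discontinuity
# --------------------------------------------------------------------------

@dataclass
class RDDSpec:
    """Sharp/fuzzy RDD configuration.

    Side models are distributional regressions of the outcome on the
    forcing variable fitted separately left and right of the cutoff within
    ``window``; ``side_formulas`` overrides the default linear-in-forcing
    predictors (e.g. with spline terms).  For fuzzy designs,
    ``treatment_var`` names the realized treatment and side-wise logistic
    models of it on the forcing variable estimate the compliance jump.
    """

    outcome: str
    forcing: str
    cutoff: float
    family: object = "Normal"
    window: tuple = None            # (lo, hi) or None for full range
    side_formulas: dict = None      # param -> formula, default "1 + forcing"
    fuzzy: bool = False
    treatment_var: str = None
    treatment_formula: str = None   # default "1 + forcing"
    min_side: int = 50
    denominator_threshold: float = 0.01

    def __post_init__(self):
        if self.window is not None:
            lo, hi = self.window
            if not lo < self.cutoff < hi:
                raise ValueError("window must contain the cutoff")
        if self.fuzzy and not self.treatment_var:
            raise ValueError("fuzzy RDD needs treatment_var")


@dataclass
class RDDResult:
    spec: RDDSpec
    effects: dict                 # functional label -> effect at the cutoff
    numerators: dict
    denominator: float
    fits: dict                    # side -> FitResult
    treatment_probs: dict         # side -> Pr(T=1 | X=c), fuzzy only
    treatment_fits: dict
    functionals: list
    data: pd.DataFrame            # window data actually used
    profile: dict
    metadata: dict

    def resample_and_refit(self, rng) -> "RDDResult":
        """Parametric bootstrap replicate: redraw outcomes from the fitted
        side distributions (and treatment from the side assignment models
        in the fuzzy case), then re-estimate everything."""
        d = self.data.copy()
        fam = self.fits["left"].family
        mask_left = d[self.spec.forcing].to_numpy(float) < self.spec.cutoff
        for side, mask in (("left", mask_left), ("right", ~mask_left)):
            sub = d.loc[mask]
            params = {p: self.fits[side].predict_params(sub)[p].to_numpy()
                      for p in fam.param_names}
            d.loc[mask, self.spec.outcome] = fam.rvs(mask.sum(), params, rng)
            if self.spec.fuzzy:
                tf = self.treatment_fits.get(side)
                if tf is None:  # deterministic side
                    continue
                pr = tf.predict_params(sub)["p"].to_numpy()
                d.loc[mask, self.spec.treatment_var] = (
                    rng.uniform(size=mask.sum()) < pr
                ).astype(float)
        est = fuzzy_rdd if self.spec.fuzzy else sharp_rdd
        return est(d, self.spec, self.functionals)


def _side_modelspec(rdd_spec: RDDSpec) -> ModelSpec:
    from .families import get_family
    fam = get_family(rdd_spec.family)
    formulas = {p: f"1 + {rdd_spec.forcing}" for p in fam.param_names}
    if rdd_spec.side_formulas:
        formulas.update(rdd_spec.side_formulas)
    return ModelSpec(outcome=rdd_spec.outcome, family=rdd_spec.family,
                     formulas=formulas)


def _split_window(data: pd.DataFrame, rdd_spec: RDDSpec):
    x = data[rdd_spec.forcing].to_numpy(float)
    if rdd_spec.window is not None:
        lo, hi = rdd_spec.window
        data = data.loc[(x >= lo) & (x <= hi)]
        x = data[rdd_spec.forcing].to_numpy(float)
    left = data.loc[x < rdd_spec.cutoff]
    right = data.loc[x >= rdd_spec.cutoff]
    for name, side in (("left", left), ("right", right)):
        if len(side) == 0:
            raise ValueError(f"no observations on the {name} side of the cutoff")
        if len(side) < rdd_spec.min_side:
            raise ValueError(
                f"only {len(side)} observations on the {name} side "
                f"(min_side={rdd_spec.min_side})"
            )
    return data, left, right


def _cutoff_profile(mspec: ModelSpec, window: pd.DataFrame, rdd_spec: RDDSpec):
    prof = profile_at_means(window, mspec, exclude=(rdd_spec.forcing,))
    vals = dict(prof.values)
    vals[rdd_spec.forcing] = rdd_spec.cutoff
    return vals


def sharp_rdd(data: pd.DataFrame, rdd_spec: RDDSpec,
              functionals=("mean",)) -> RDDResult:
    """Sharp RDD: side-wise distributional fits; for each functional the
    effect is its value under the right-side model at the cutoff minus the
    left-side value.  Valid under continuity of the counterfactual
    conditional densities at the cutoff (recorded in the metadata)."""
    window, left, right = _split_window(data, rdd_spec)
    mspec = _side_modelspec(rdd_spec)
    fits = {"left": fit(mspec, left), "right": fit(mspec, right)}
    prof = _cutoff_profile(mspec, window, rdd_spec)
    point = pd.DataFrame([prof])
    fam = fits["left"].family
    effects, numerators = {}, {}
    for fl in functionals:
        fs = FunctionalSpec.parse(fl)
        vals = {}
        for side in ("left", "right"):
            pp = fits[side].predict_params(point)
            ps = {k: float(pp[k].iloc[0]) for k in fam.param_names}
            vals[side] = evaluate(fs, fam, ps)
        numerators[fs.label()] = vals["right"] - vals["left"]
        effects[fs.label()] = vals["right"] - vals["left"]
    return RDDResult(
        spec=rdd_spec, effects=effects, numerators=numerators,
        denominator=1.0, fits=fits, treatment_probs={}, treatment_fits={},
        functionals=list(functionals), data=window, profile=prof,
        metadata={"assumption": "continuity of the conditional outcome "
                                "densities at the cutoff", "design": "sharp"},
    )


def fuzzy_rdd(data: pd.DataFrame, rdd_spec: RDDSpec,
              functionals=("mean",)) -> RDDResult:
    """Fuzzy RDD: sharp-style functional differences scaled by the jump in
    treatment probability at the cutoff, estimated by side-wise logistic
    regressions of the treatment on the forcing variable."""
    if not rdd_spec.fuzzy:
        rdd_spec = replace(rdd_spec, fuzzy=True)
    sharp = sharp_rdd(data, replace(rdd_spec, fuzzy=False), functionals)
    window, left, right = _split_window(data, rdd_spec)
    tvar = rdd_spec.treatment_var
    tform = rdd_spec.treatment_formula or f"1 + {rdd_spec.forcing}"
    probs, tfits = {}, {}
    point = pd.DataFrame([sharp.profile])
    for side, sub in (("left", left), ("right", right)):
        tvals = sub[tvar].to_numpy(float)
        if np.all(tvals == tvals[0]):
            probs[side] = float(tvals[0])  # deterministic assignment
            tfits[side] = None
            continue
        tspec = ModelSpec(outcome=tvar, family="Bernoulli",
                          formulas={"p": tform})
        tf = fit(tspec, sub)
        tfits[side] = tf
        probs[side] = float(tf.predict_params(point)["p"].iloc[0])
    denom = probs["right"] - probs["left"]
    if abs(denom) < rdd_spec.denominator_threshold:
        raise ValueError(
            f"treatment probability jump at the cutoff is {denom:.4f}; the "
            "fuzzy RDD requires that the probability of treatment changes "
            "discontinuously at the cutoff value"
        )
    effects = {k: v / denom for k, v in sharp.numerators.items()}
    return RDDResult(
        spec=rdd_spec, effects=effects, numerators=dict(sharp.numerators),
        denominator=denom, fits=sharp.fits, treatment_probs=probs,
        treatment_fits=tfits, functionals=list(functionals), data=window,
        profile=sharp.profile,
        metadata={**sharp.metadata, "design": "fuzzy"},
    )


def rdd_window_sensitivity(data: pd.DataFrame, rdd_spec: RDDSpec,
                           functionals=("mean",), half_widths=None):
    """Re-estimate the RDD over a grid of symmetric windows around the
    cutoff and tabulate the effects — the recommended bandwidth check."""
    x = data[rdd_spec.forcing].to_numpy(float)
    if half_widths is None:
        full = max(rdd_spec.cutoff - x.min(), x.max() - rdd_spec.cutoff)
        half_widths = np.linspace(0.4, 1.0, 4) * full
    rows = []
    est = fuzzy_rdd if rdd_spec.fuzzy else sharp_rdd
    for h in half_widths:
        w = (rdd_spec.cutoff - h, rdd_spec.cutoff + h)
        try:
            res = est(data, replace(rdd_spec, window=w), functionals)
            row = {"half_width": float(h), "n": len(res.data), **res.effects}
        except ValueError as exc:
            row = {"half_width": float(h), "n": 0, "error": str(exc)}
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# FGLS vulnerability baseline
# --------------------------------------------------------------------------

def fgls_vulnerability(data: pd.DataFrame, covariates, z: float,
                       outcome: str = "y"):
    """3-step FGLS log-normal vulnerability baseline.

    Step 1: OLS of ln y on x.  Step 2: OLS of the squared residuals on x to
    get fitted error variances.  Step 3: weighted re-estimation of the
    variance and then the mean equation with the fitted variances as
    weights.  Vulnerability is Phi((ln z - mean_i)/sd_i).  Rows whose
    fitted variance is non-positive are clamped to a floor (count
    reported).  This is a baseline approximation to the simultaneous
    distributional-model estimate, not a replication of any particular
    FGLS variant.
    """
    y = data[outcome].to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("FGLS vulnerability requires a positive outcome")
    if z <= 0:
        raise ValueError("poverty line z must be positive")
    ly = np.log(y)
    X = np.column_stack([np.ones(len(y))] +
                        [data[c].to_numpy(float) for c in covariates])

    def ols(yv, w=None):
        Xw = X if w is None else X * w[:, None]
        yw = yv if w is None else yv * w
        return np.linalg.lstsq(Xw, yw, rcond=None)[0]

    b1 = ols(ly)                               # step 1
    e2 = (ly - X @ b1) ** 2
    bv = ols(e2)                               # step 2
    v0 = X @ bv
    floor = 1e-8
    n_clamped = int(np.sum(v0 <= floor))
    v0 = np.clip(v0, floor, None)
    w = 1.0 / np.sqrt(v0)
    bv2 = ols(e2, w)                           # step 3: reweighted variance eq.
    v1 = X @ bv2
    n_clamped += int(np.sum(v1 <= floor))
    v1 = np.clip(v1, floor, None)
    bm = ols(ly, 1.0 / np.sqrt(v1))            # step 3: reweighted mean eq.
    mean = X @ bm
    prob = stats.norm.cdf((np.log(z) - mean) / np.sqrt(v1))
    return pd.DataFrame({
        "fitted_mean_log": mean,
        "fitted_var_log": v1,
        "vulnerability": prob,
        "vulnerable": prob >= 0.5,
    }, index=data.index), {"n_clamped": n_clamped,
                           "coef_mean": bm, "coef_var": bv2}
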