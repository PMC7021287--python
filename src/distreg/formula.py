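"""Additive-predictor terms: parsing, design matrices and penalty blocks.

A predictor for one distribution parameter is a sum of terms:

``"1 + treat + povindex + s(age, k=10) + cluster(village) + a:b + C(educ)"``

- ``1``                intercept (include explicitly; no implicit intercept)
- bare name            linear effect for numeric columns, reference-coded
                       categorical for non-numeric columns
- ``C(x)``             force categorical (reference coding, smallest level
                       is the reference)
- ``a:b``              elementwise product of two numeric columns
- ``s(x, k, degree, order, lam)``   P-spline: B-spline basis of size ``k``
                       with a difference penalty of the given ``order`` and
                       penalty weight ``lam``
- ``cluster(g, prec)`` one indicator column per cluster level with a ridge
                       penalty of weight ``prec`` (a Gaussian random
                       intercept in penalized-likelihood form)

When the predictor also contains an intercept, spline blocks are
reparameterized with a sum-to-zero constraint (projection onto the null
space of the basis column means) so the smooth cannot absorb the constant;
without an intercept the raw ``k``-column basis is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class TermSpec:
    """One additive term of a distribution parameter's predictor."""

    kind: str  # intercept | linear | categorical | spline | cluster | interaction
    variables: tuple = ()
    k: int = 10
    degree: int = 3
    order: int = 2
    lam: float = 1.0
    precision: float = 1.0

    def __post_init__(self):
        if self.kind not in (
            "intercept", "linear", "categorical", "spline", "cluster", "interaction"
        ):
            raise DesignError(f"unknown term kind {self.kind!r}")
        if self.kind == "spline" and self.k < self.degree + 2:
            raise DesignError(
                f"spline basis size k={self.k} must be >= degree+2={self.degree + 2}"
            )

    def label(self):
        if self.kind == "intercept":
            return "(Intercept)"
        if self.kind == "interaction":
            return ":".join(self.variables)
        if self.kind == "spline":
            return f"s({self.variables[0]})"
        if self.kind == "cluster":
            return f"cluster({self.variables[0]})"
        return self.variables[0]


_FUNC_RE = re.compile(r"^(s|cluster|C)\((.*)\)$")


def _parse_kwargs(parts):
    kw = {}
    for p in parts:
        key, _, val = p.partition("=")
        kw[key.strip()] = float(val)
    return kw


def parse_formula(formula: str) -> list:
    """Parse a predictor formula string into an ordered list of TermSpecs."""
    terms = []
    for raw in str(formula).split("+"):
        tok = raw.strip()
        if not tok:
            continue
        if tok == "1":
            terms.append(TermSpec("intercept"))
            continue
        if tok == "0":
            continue
        m = _FUNC_RE.match(tok)
        if m:
            func, inner = m.groups()
            parts = [p.strip() for p in inner.split(",") if p.strip()]
            var, opts = parts[0], _parse_kwargs(parts[1:])
            if func == "s":
                terms.append(TermSpec(
                    "spline", (var,),
                    k=int(opts.get("k", 10)),
                    degree=int(opts.get("degree", 3)),
                    order=int(opts.get("order", 2)),
                    lam=float(opts.get("lam", 1.0)),
                ))
            elif func == "cluster":
                terms.append(TermSpec(
                    "cluster", (var,), precision=float(opts.get("prec", 1.0))
                ))
            else:
                terms.append(TermSpec("categorical", (var,)))
            continue
        if ":" in tok:
            a, b = (p.strip() for p in tok.split(":", 1))
            terms.append(TermSpec("interaction", (a, b)))
            continue
        terms.append(TermSpec("linear", (tok,)))  # dtype resolved at build time
    return terms


def _check_column(data: pd.DataFrame, var: str):
    if var not in data.columns:
        raise DesignError(f"unknown variable {var!r}")
    col = data[var]
    if col.isna().any():
        rows = [int(i) for i in np.flatnonzero(col.isna().to_numpy())[:10]]
        raise DesignError(f"missing values in {var!r} at rows {rows}")
    return col


def _bspline_knots(lo, hi, k, degree):
    if hi <= lo:
        raise DesignError("spline covariate is constant; smooth is not identifiable")
    dx = (hi - lo) / (k - degree)
    return lo + dx * np.arange(-degree, k + 1)


@dataclass
class BuiltTerm:
    """A TermSpec bound to training data (levels, knots, constraints)."""

    spec: TermSpec
    labels: list
    penalty: np.ndarray = None  # penalty matrix on this block, or None
    weight: float = 0.0
    state: dict = field(default_factory=dict)

    @property
    def ncol(self):
        return len(self.labels)

    def matrix(self, data: pd.DataFrame, training: bool) -> np.ndarray:
        sp, st = self.spec, self.state
        n = len(data)
        if sp.kind == "intercept":
            return np.ones((n, 1))
        if sp.kind == "linear":
            return _check_column(data, sp.variables[0]).to_numpy(float)[:, None]
        if sp.kind == "interaction":
            a = _check_column(data, sp.variables[0]).to_numpy(float)
            b = _check_column(data, sp.variables[1]).to_numpy(float)
            return (a * b)[:, None]
        if sp.kind == "categorical":
            col = _check_column(data, sp.variables[0])
            vals = col.to_numpy()
            unseen = set(np.unique(vals)) - set(st["levels"])
            if unseen:
                raise DesignError(
                    f"unseen level(s) {sorted(map(str, unseen))} in {sp.variables[0]!r}"
                )
            return np.column_stack(
                [(vals == lev).astype(float) for lev in st["levels"][1:]]
            ) if len(st["levels"]) > 1 else np.empty((n, 0))
        if sp.kind == "cluster":
            col = _check_column(data, sp.variables[0])
            vals = col.to_numpy()
            levels = st["levels"]
            if training:
                pass
            else:
                # prediction at an unseen cluster gets a zero (prior-mean) effect
                pass
            idx = {lev: j for j, lev in enumerate(levels)}
            Z = np.zeros((n, len(levels)))
            for i, v in enumerate(vals):
                j = idx.get(v)
                if j is not None:
                    Z[i, j] = 1.0
            return Z
        # spline
        x = _check_column(data, sp.variables[0]).to_numpy(float)
        B = BSpline.design_matrix(
            np.clip(x, st["lo"], st["hi"]), st["knots"], sp.degree
        ).toarray()
        C = st.get("constraint")
        return B @ C if C is not None else B


def build_term(spec: TermSpec, data: pd.DataFrame, center_splines: bool) -> BuiltTerm:
    if spec.kind == "intercept":
        return BuiltTerm(spec, ["(Intercept)"])
    if spec.kind == "linear":
        col = _check_column(data, spec.variables[0])
        if not pd.api.types.is_numeric_dtype(col):
            # non-numeric bare name promotes to categorical
            return build_term(
                TermSpec("categorical", spec.variables), data, center_splines
            )
        return BuiltTerm(spec, [spec.variables[0]])
    if spec.kind == "interaction":
        for v in spec.variables:
            _check_column(data, v)
        return BuiltTerm(spec, [":".join(spec.variables)])
    if spec.kind == "categorical":
        col = _check_column(data, spec.variables[0])
        levels = sorted(pd.unique(col.to_numpy()).tolist())
        labels = [f"{spec.variables[0]}[{lev}]" for lev in levels[1:]]
        if not labels:
            raise DesignError(
                f"categorical {spec.variables[0]!r} has a single level"
            )
        return BuiltTerm(spec, labels, state={"levels": levels})
    if spec.kind == "cluster":
        col = _check_column(data, spec.variables[0])
        levels = sorted(pd.unique(col.to_numpy()).tolist())
        labels = [f"cluster({spec.variables[0]})[{lev}]" for lev in levels]
        S = np.eye(len(levels))
        return BuiltTerm(
            spec, labels, penalty=S, weight=spec.precision, state={"levels": levels}
        )
    # spline
    x = _check_column(data, spec.variables[0]).to_numpy(float)
    lo, hi = float(np.min(x)), float(np.max(x))
    knots = _bspline_knots(lo, hi, spec.k, spec.degree)
    state = {"lo": lo, "hi": hi, "knots": knots}
    D = np.diff(np.eye(spec.k), n=spec.order, axis=0)
    S = D.T @ D
    ncol = spec.k
    if center_splines:
        B = BSpline.design_matrix(x, knots, spec.degree).toarray()
        c = B.mean(axis=0)[None, :]
        C = null_space(c)  # k x (k-1), orthonormal
        state["constraint"] = C
        S = C.T @ S @ C
        ncol = spec.k - 1
    labels = [f"s({spec.variables[0]}).{j + 1}" for j in range(ncol)]
    return BuiltTerm(spec, labels, penalty=S, weight=spec.lam, state=state)


class ParamDesign:
    """Design matrix + penalty blocks for one distribution parameter."""

    def __init__(self, terms, data: pd.DataFrame):
        if isinstance(terms, str):
            terms = parse_formula(terms)
        self.terms = list(terms)
        has_intercept = any(t.kind == "intercept" for t in self.terms)
        self.built = [build_term(t, data, center_splines=has_intercept)
                      for t in self.terms]
        self.labels = [lab for bt in self.built for lab in bt.labels]
        self.ncol = len(self.labels)
        # penalty blocks: (start, stop, S, weight)
        self.penalties = []
        pos = 0
        for bt in self.built:
            if bt.penalty is not None:
                self.penalties.append((pos, pos + bt.ncol, bt.penalty, bt.weight))
            pos += bt.ncol

    def matrix(self, data: pd.DataFrame, training: bool = False) -> np.ndarray:
        if len(data) == 0:
            raise DesignError("empty data table")
        return np.hstack([bt.matrix(data, training) for bt in self.built])

    def penalty_matrix(self) -> np.ndarray:
        """Full (weighted) penalty matrix for this block of coefficients."""
        S = np.zeros((self.ncol, self.ncol))
        for a, b, Sb, w in self.penalties:
            S[a:b, a:b] += w * Sb
        return S

    @property
    def penalized_cols(self):
        mask = np.zeros(self.ncol, dtype=bool)
        for a, b, _, _ in self.penalties:
            mask[a:b] = True
        return mask


def build_design(data: pd.DataFrame, terms):
    """Convenience: (matrix, penalty blocks, labels) for a term list."""
    d = ParamDesign(terms, data)
    return d.matrix(data, training=True), d.penalties, d.labels
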