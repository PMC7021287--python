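"""End-to-end orchestration: config validation, the fit/diagnose/effects
pipeline, and model comparison.

A :class:`RunConfig` encodes the analysis workflow: choose a response
family, specify per-parameter predictors, fit and diagnose, then report
treatment effects on the requested distributional functionals with
bootstrap intervals.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import designs, inference
from .core import ModelSpec, fit, information_criteria
from .diagnose import qq_points, quantile_residuals, residual_summary
from .effects import conditional_density_curve, marginal_effect, profile_at_means
from .families import get_family
from .io import read_dataset, write_dataset

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "data", "outcome", "family", "formulas", "links", "treatment", "design",
    "functionals", "bootstrap", "output_dir", "column_types", "csv", "seed",
}
_DESIGN_TYPES = {"rct", "did", "panel", "iv", "rdd"}
_BOOT_METHODS = {"parametric", "cluster", "iv", "rdd", "none"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    data: str
    outcome: str
    family: str = "Normal"
    formulas: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)
    treatment: str = None
    design: dict = field(default_factory=lambda: {"type": "rct"})
    functionals: list = field(default_factory=lambda: ["mean", "variance"])
    bootstrap: dict = field(default_factory=lambda: {"method": "none"})
    output_dir: str = None
    column_types: dict = field(default_factory=dict)
    csv: dict = field(default_factory=dict)
    seed: int = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self):
        get_family(self.family)  # raises for unknown names
        dtype = self.design.get("type", "rct")
        if dtype not in _DESIGN_TYPES:
            raise ConfigError(
                f"design type {dtype!r} not in {sorted(_DESIGN_TYPES)}")
        method = self.bootstrap.get("method", "none")
        if method not in _BOOT_METHODS:
            raise ConfigError(
                f"bootstrap method {method!r} not in {sorted(_BOOT_METHODS)}")
        if dtype in ("rct", "did", "panel", "iv") and not self.treatment:
            raise ConfigError(f"design {dtype!r} needs a treatment variable")
        from .functionals import FunctionalSpec
        for fl in self.functionals:
            text = str(fl)
            if "z=auto" in text:  # resolved against the data at run time
                text = text.split(":z=auto")[0] + ":z=1"
            FunctionalSpec.parse(text)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(outcome=self.outcome, family=self.family,
                         formulas=dict(self.formulas), links=dict(self.links))


@dataclass
class RunResult:
    fit: object
    diagnostics: pd.Series
    effects: pd.DataFrame
    profile: object
    artifacts: dict


def _resolve_functionals(functionals, data, outcome):
    """Expand 'vulnerability:z=auto<frac>' against the observed sample."""
    from .functionals import poverty_line
    out = []
    for fl in functionals:
        text = str(fl)
        if "z=auto" in text:
            frac = float(text.split("z=auto")[1] or 0.6)
            z = poverty_line(data[outcome].to_numpy(float), frac)
            text = text.split(":z=auto")[0] + f":z={z:g}"
        out.append(text)
    return out


def run(config: RunConfig, data: pd.DataFrame = None) -> RunResult:
    """Execute the full workflow for one configuration."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    t0 = time.time()
    if data is None:
        data = read_dataset(config.data, config.column_types,
                            **{k: v for k, v in config.csv.items()
                               if k in ("sep", "decimal")})
    logger.info("stage=load rows=%d elapsed=%.2fs", len(data), time.time() - t0)

    spec = config.model_spec()
    dtype = config.design.get("type", "rct")
    if dtype == "did":
        spec = designs.did_augment(spec, config.treatment,
                                   config.design["period"], data)
    elif dtype == "panel":
        data, spec = designs.mundlak_augment(
            data, spec, config.design["cluster"],
            config.design.get("variables", []))

    functionals = _resolve_functionals(config.functionals, data, config.outcome)

    if dtype == "rdd":
        return _run_rdd(config, data, functionals, t0)

    if dtype == "iv":
        iv_spec = designs.IVSpec(
            endogenous=config.design["endogenous"],
            exogenous=config.design.get("exogenous", []),
            instruments=config.design["instruments"],
        )
        first = designs.tsri_first_stage(data, iv_spec)
        data = first.data
        fitted = designs.tsri_second_stage(spec, data, first.residual_columns)
        spec = fitted.spec
    else:
        fitted = fit(spec, data)
    logger.info("stage=fit loglik=%.2f edf=%.1f elapsed=%.2fs",
                fitted.loglik, fitted.edf, time.time() - t0)

    resid = quantile_residuals(fitted, data, seed=config.seed)
    diag = residual_summary(resid)
    logger.info("stage=diagnose filliben=%.4f elapsed=%.2fs",
                diag["filliben"], time.time() - t0)

    prof = profile_at_means(data, spec, exclude=(config.treatment,))
    labels = functionals

    def statistic(fr, d):
        return np.array([
            marginal_effect(fr, prof, config.treatment, fl) for fl in labels
        ])

    estimates = statistic(fitted, data)
    method = config.bootstrap.get("method", "none")
    B = int(config.bootstrap.get("B", inference.DEFAULT_B))
    seed = config.bootstrap.get("seed", config.seed)
    lo = hi = [np.nan] * len(labels)
    if method == "parametric" or (method == "iv" and dtype != "iv"):
        boot = inference.parametric_bootstrap(fitted, data, statistic, B, seed)
        lo, hi = inference.percentile_ci(boot)
    elif method == "cluster":
        boot = inference.pairs_cluster_bootstrap(
            spec, data, config.design["cluster"], statistic, B, seed)
        lo, hi = inference.percentile_ci(boot)
    elif method == "iv":
        boot = inference.iv_bootstrap(
            iv_spec, config.model_spec(), data, statistic,
            N_b=int(config.bootstrap.get("N_b", 10)),
            N_d=int(config.bootstrap.get("N_d", max(B // 10, 2))), seed=seed)
        lo, hi = inference.percentile_ci(boot)
    effects = pd.DataFrame({
        "functional": labels, "estimate": estimates,
        "lower": np.asarray(lo, dtype=float),
        "upper": np.asarray(hi, dtype=float),
    })
    logger.info("stage=effects n_functionals=%d elapsed=%.2fs",
                len(labels), time.time() - t0)

    artifacts = {}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        log_lines = [
            f"stage=load rows={len(data)}",
            f"stage=fit loglik={fitted.loglik:.4f} edf={fitted.edf:.2f} "
            f"converged={fitted.converged}",
            f"stage=diagnose filliben={diag['filliben']:.5f} "
            f"clamped={resid.n_clamped}",
            f"stage=effects functionals={len(labels)} method={method} "
            f"elapsed={time.time() - t0:.2f}s",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n",
                                     encoding="utf-8")
        artifacts["log"] = out / "run.log"
        artifacts["effects"] = write_dataset(effects, out / "effects.csv")
        artifacts["diagnostics"] = write_dataset(
            diag.rename("value").rename_axis("statistic").reset_index(),
            out / "diagnostics.csv")
        artifacts["qq"] = write_dataset(qq_points(resid), out / "qq.csv")
        if config.treatment:
            curve = conditional_density_curve(fitted, prof, config.treatment)
            artifacts["density"] = write_dataset(curve, out / "density.csv")
        coef = fitted.coef_table()
        artifacts["coefficients"] = write_dataset(coef, out / "coefficients.csv")
    return RunResult(fit=fitted, diagnostics=diag, effects=effects,
                     profile=prof, artifacts=artifacts)


def _run_rdd(config: RunConfig, data, functionals, t0):
    d = config.design
    rdd_spec = designs.RDDSpec(
        outcome=config.outcome, forcing=d["forcing"],
        cutoff=float(d["cutoff"]), family=config.family,
        window=tuple(d["window"]) if d.get("window") else None,
        fuzzy=bool(d.get("fuzzy", False)),
        treatment_var=config.treatment if d.get("fuzzy") else None,
    )
    est = designs.fuzzy_rdd if rdd_spec.fuzzy else designs.sharp_rdd
    res = est(data, rdd_spec, functionals)
    labels = list(res.effects)
    method = config.bootstrap.get("method", "none")
    lo = hi = [np.nan] * len(labels)
    if method != "none":
        boot = inference.rdd_bootstrap(
            res, lambda r: np.array([r.effects[k] for k in labels]),
            B=int(config.bootstrap.get("B", inference.DEFAULT_B)),
            seed=config.bootstrap.get("seed", config.seed))
        lo, hi = inference.percentile_ci(boot)
    effects = pd.DataFrame({
        "functional": labels,
        "estimate": [res.effects[k] for k in labels],
        "lower": np.asarray(lo, dtype=float),
        "upper": np.asarray(hi, dtype=float),
    })
    logger.info("stage=rdd elapsed=%.2fs", time.time() - t0)
    artifacts = {}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts["effects"] = write_dataset(effects, out / "effects.csv")
    return RunResult(fit=res, diagnostics=None, effects=effects,
                     profile=res.profile, artifacts=artifacts)


def compare_models(configs, data: pd.DataFrame = None) -> pd.DataFrame:
    """Side-by-side residual diagnostics and information criteria.

    All configs must name the same data source; comparison across
    different data is refused.
    """
    configs = [RunConfig.from_dict(c) if isinstance(c, dict) else c
               for c in configs]
    if len(configs) < 2:
        raise ConfigError("model comparison needs at least two configs")
    if len({c.data for c in configs}) > 1:
        raise ConfigError("configs compare models on different data files")
    if data is None:
        data = read_dataset(configs[0].data, configs[0].column_types)
    rows = []
    for c in configs:
        fitted = fit(c.model_spec(), data)
        resid = quantile_residuals(fitted, data, seed=c.seed)
        summ = residual_summary(resid)
        aic, bic = information_criteria(fitted)
        rows.append({"family": c.family, **summ.to_dict(),
                     "aic": aic, "bic": bic, "loglik": fitted.loglik,
                     "edf": fitted.edf})
    return pd.DataFrame(rows)
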