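"""Configuration-driven analysis pipeline and result serialization."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .averaging import (compute_weights, ma_bmd_estimates, ma_bmdl_buckland,
                        ma_bmdl_weighted, ma_bootstrap_bmdl)
from .bmdcore import BMRSpec, bmd_se_delta, solve_bmd
from .data import DoseResponseData, read_table
from .exceptions import BmdError, InvalidModelError
from .models import fit_model, overdispersion_ratio
from .uncertainty import (bmdl_delta, bmdl_inverse_regression, bootstrap_bmd,
                          sandwich_vcov, BMDL_METHOD_CODES)

log = logging.getLogger("bmdkit")

__all__ = ["AnalysisConfig", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str
    models: List[str]
    bmr: float
    definition: str
    response_kind: Optional[str] = None
    column_mapping: Dict[str, str] = field(default_factory=dict)
    background_type: str = "model_based"
    p0: Optional[float] = None
    x0: Optional[float] = None
    k_sd: Optional[float] = None
    bmdl_method: str = "delta"
    level: float = 0.95           # one-sided
    n_boot: int = 1000
    seed: int = 0
    sandwich: bool = False
    cluster_robust: bool = False
    ma: Optional[str] = None      # estimate | curve
    ma_bmdl: str = "buckland"     # buckland | weighted | boot
    output_json: Optional[str] = None
    output_curves: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _bmr_spec(cfg: AnalysisConfig) -> BMRSpec:
    return BMRSpec(bmr=cfg.bmr, definition=cfg.definition,
                   background_type=cfg.background_type, p0_fixed=cfg.p0,
                   x0=cfg.x0, k_sd=cfg.k_sd)


def _finite_or_null(x):
    if x is None:
        return {"value": None, "reason": "not computed"}
    if isinstance(x, float) and not math.isfinite(x):
        return {"value": None, "reason": "non-finite"}
    return x


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Fit the requested models, compute BMD/BMDL per the config, and
    optionally model-average; returns (and optionally writes) a JSON-able
    result bundle plus a CSV dose grid of fitted curves."""
    if not 0.5 < cfg.level < 1.0:
        raise InvalidModelError(
            "level is the one-sided BMDL confidence level and must lie in "
            "(0.5, 1); two-sided inputs like 0.05 should be given as 0.95")
    data = read_table(cfg.input_path, response_kind=cfg.response_kind,
                      mapping=cfg.column_mapping)
    bmr = _bmr_spec(cfg)
    method = BMDL_METHOD_CODES.get(cfg.bmdl_method, cfg.bmdl_method)

    per_model = []
    fits = []
    for code in cfg.models:
        entry = {"model": code}
        try:
            fit = fit_model(data, code)
            vcov = None
            if cfg.sandwich:
                vcov = sandwich_vcov(fit, data,
                                     cluster_robust=cfg.cluster_robust
                                     ).vcov_sandwich
                log.info("%s: sandwich covariance in use", code)
            est = solve_bmd(fit, bmr)
            est.se = bmd_se_delta(fit, est, spec=bmr, vcov=vcov)
            if est.extrapolated:
                log.warning("%s: BMD %.4g beyond the observed dose range",
                            code, est.bmd)
            if method == "delta":
                bl = bmdl_delta(fit, est, level=cfg.level)
            elif method == "delta_log":
                bl = bmdl_delta(fit, est, level=cfg.level, scale="log")
            elif method == "inverse_regression":
                bl = bmdl_inverse_regression(fit, bmr, level=cfg.level,
                                             vcov=vcov)
            elif method.startswith("boot"):
                kind = method.replace("boot_", "")
                bl = bootstrap_bmd(data, fit.spec, bmr, kind=kind,
                                   n_boot=cfg.n_boot, level=cfg.level,
                                   seed=cfg.seed)
                if bl.n_failed:
                    log.info("%s: %d bootstrap replicates dropped", code,
                             bl.n_failed)
            else:
                raise InvalidModelError(f"unknown BMDL method {cfg.bmdl_method!r}")
            entry.update(
                bmd=est.bmd, bmd_se=est.se, bmdl=bl.bmdl,
                target_level=est.target_level, p0=est.p0,
                aic=fit.aic, bic=fit.bic, loglik=fit.loglik,
                direction=fit.direction, converged=fit.converged,
                extrapolated=est.extrapolated,
            )
            if fit.spec.distribution in ("binomial", "poisson"):
                entry["overdispersion_ratio"] = overdispersion_ratio(fit)
            fits.append((code, fit, est))
        except BmdError as exc:
            entry["error"] = str(exc)
            log.warning("%s failed: %s", code, exc)
        per_model.append(entry)

    if not fits:
        raise InvalidModelError(
            "no model produced a usable fit: "
            + "; ".join(e.get("error", "?") for e in per_model))

    result = {
        "software": {"name": "bmdkit", "version": __version__},
        "config": asdict(cfg),
        "seed": cfg.seed,
        "models": [
            {k: _finite_or_null(v) for k, v in e.items()} for e in per_model
        ],
    }

    ok = [e for e in per_model if "error" not in e]
    if cfg.ma:
        if len(fits) < 2:
            raise InvalidModelError("model averaging needs >= 2 usable fits")
        ws = compute_weights([e["aic"] for e in ok], scheme="aic",
                             model_ids=[e["model"] for e in ok])
        ma_block = {"weights": dict(zip(ws.model_ids, ws.weights.tolist()))}
        if cfg.ma_bmdl == "boot" or cfg.ma == "curve":
            res = ma_bootstrap_bmdl(
                data, [c for c, _, _ in fits], bmr,
                approach="curve_avg" if cfg.ma == "curve" else "estimate_avg",
                n_boot=cfg.n_boot, level=cfg.level, seed=cfg.seed)
            ma_block.update(bmd=res.bmd_ma, bmdl=res.bmdl_ma,
                            method_bmdl="bootstrap", n_failed=res.n_failed)
        else:
            bmds = [e["bmd"] for e in ok]
            bmd_ma = ma_bmd_estimates(bmds, ws)
            if cfg.ma_bmdl == "weighted":
                bmdl = ma_bmdl_weighted([e["bmdl"] for e in ok], ws)
            else:
                bmdl = ma_bmdl_buckland(bmds, [e["bmd_se"] ** 2 for e in ok],
                                        ws, level=cfg.level)
            ma_block.update(bmd=bmd_ma, bmdl=bmdl, method_bmdl=cfg.ma_bmdl)
        result["model_averaging"] = {
            k: _finite_or_null(v) for k, v in ma_block.items()
        }

    if cfg.output_curves and fits:
        _write_curves(cfg, data, fits)
        result["curves_csv"] = cfg.output_curves
    if cfg.output_json:
        with open(cfg.output_json, "w") as fh:
            json.dump(result, fh, indent=1, default=_json_default)
        log.info("wrote %s", cfg.output_json)
    return result


def _write_curves(cfg, data: DoseResponseData, fits):
    """CSV dose grid with fitted responses and a one-sided delta band."""
    from scipy import stats as _st
    d_max = float(data.dose.max())
    pos = data.dose[data.dose > 0]
    d_min = float(pos.min()) if len(pos) else d_max / 100.0
    grid = np.concatenate([[0.0], np.geomspace(d_min / 10.0, d_max, 99)])
    z = _st.norm.ppf(cfg.level)
    frames = {"dose": grid}
    for code, fit, _est in fits:
        mu = fit.predict(grid)
        se = np.empty_like(grid)
        beta = fit.beta
        for i, dd in enumerate(grid):
            g = np.empty(len(beta))
            for j in range(len(beta)):
                h = 1e-6 * (1.0 + abs(beta[j]))
                bp = beta.copy(); bp[j] += h
                bm = beta.copy(); bm[j] -= h
                g[j] = (float(fit.mean_at(bp, dd)) -
                        float(fit.mean_at(bm, dd))) / (2 * h)
            se[i] = math.sqrt(max(float(g @ fit.vcov @ g), 0.0))
        sign = 1.0 if fit.direction == "increasing" else -1.0
        frames[f"{code}_fitted"] = mu
        frames[f"{code}_band"] = mu + sign * z * se
    pd.DataFrame(frames).to_csv(cfg.output_curves, index=False)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
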