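"""Model-averaged BMD and BMDL.

Weights come from information criteria, ``w_k = exp(-Delta_k/2) /
sum_i exp(-Delta_i/2)`` with ``Delta_k`` the AIC (or BIC) difference to
the best model; user weights are renormalised.  An alternative
``exp(-Delta)`` kernel is available behind a flag.

The model-averaged BMD is either the weighted average of per-model BMDs
(estimate averaging) or the BMD solved on the weighted average of the
fitted curves themselves (curve averaging).  The MA BMDL comes from the
Buckland variance inequality, from weighting per-model BMDLs, or from a
bootstrap that recomputes weights inside every replicate — the only
option for curve averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .bmdcore import BMRSpec, background_level, solve_bmd, target_response
from .data import DoseResponseData
from .exceptions import ConvergenceError, InvalidModelError, NotReachableError
from .models import ModelFit, ModelSpec, fit_model
from .uncertainty import _replicate_rngs, resample

__all__ = [
    "WeightSet", "AveragingResult", "AveragedCurve", "compute_weights",
    "ma_bmd_estimates", "ma_bmdl_buckland", "ma_bmdl_weighted", "ma_curve",
    "ma_bootstrap_bmdl",
]

_norm = stats.norm


@dataclass
class WeightSet:
    model_ids: List[str]
    weights: np.ndarray
    deltas: np.ndarray
    criterion: str  # aic | bic | user

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclass
class AveragingResult:
    bmd_ma: float
    bmdl_ma: Optional[float]
    method_bmd: str           # estimate_avg | curve_avg
    method_bmdl: Optional[str]  # buckland | weighted_bmdl | bootstrap
    weights: WeightSet
    per_model: Optional[dict] = None
    n_boot: int = 0
    n_failed: int = 0
    samples: Optional[np.ndarray] = None


def compute_weights(criteria: Sequence[float], scheme: str = "aic",
                    user_weights: Optional[Sequence[float]] = None,
                    model_ids: Optional[Sequence[str]] = None,
                    kernel: str = "half_delta") -> WeightSet:
    """Information-criterion weights.

    ``kernel='half_delta'`` is the conventional ``exp(-Delta/2)``;
    ``kernel='delta'`` uses ``exp(-Delta)``.
    """
    criteria = np.asarray(criteria, float)
    ids = list(model_ids) if model_ids is not None else \
        [f"model_{i}" for i in range(len(criteria))]
    if scheme == "user":
        if user_weights is None:
            raise InvalidModelError("scheme='user' requires user_weights")
        w = np.asarray(user_weights, float)
        if np.any(w < 0):
            raise InvalidModelError("user weights must be non-negative")
        if w.sum() <= 0:
            raise InvalidModelError("user weights sum to zero")
        return WeightSet(ids, w / w.sum(), np.zeros(len(w)), "user")
    if scheme not in ("aic", "bic"):
        raise InvalidModelError("scheme must be 'aic', 'bic' or 'user'")
    finite = np.isfinite(criteria)
    if not finite.any():
        raise InvalidModelError("all information criteria are non-finite")
    deltas = criteria - np.nanmin(criteria[finite])
    scale = 0.5 if kernel == "half_delta" else 1.0
    raw = np.where(finite, np.exp(-scale * deltas), 0.0)
    return WeightSet(ids, raw / raw.sum(), deltas, scheme)


def ma_bmd_estimates(per_model_bmds: Sequence[float], ws: WeightSet) -> float:
    """Weighted average of per-model BMD estimates."""
    bmds = np.asarray(per_model_bmds, float)
    if len(bmds) != ws.K:
        raise InvalidModelError("BMD vector length does not match weights")
    if np.any(~np.isfinite(bmds) & (ws.weights > 0)):
        raise InvalidModelError("non-finite BMD with positive weight")
    return float(np.sum(np.where(ws.weights > 0, bmds, 0.0) * ws.weights))


def ma_bmdl_buckland(per_model_bmds: Sequence[float],
                     per_model_vars: Sequence[float], ws: WeightSet,
                     level: float = 0.95) -> float:
    """Wald MA BMDL with the Buckland variance-inequality SE:
    ``se_MA = sum_k w_k sqrt(var_k + (BMD_k - BMD_MA)^2)``."""
    bmds = np.asarray(per_model_bmds, float)
    vars_ = np.asarray(per_model_vars, float)
    if np.any(vars_ < 0):
        raise InvalidModelError("negative per-model BMD variance")
    bmd_ma = ma_bmd_estimates(bmds, ws)
    se_ma = float(np.sum(ws.weights * np.sqrt(vars_ + (bmds - bmd_ma) ** 2)))
    return max(0.0, bmd_ma - _norm.ppf(level) * se_ma)


def ma_bmdl_weighted(per_model_bmdls: Sequence[float], ws: WeightSet) -> float:
    """Weighted average of the per-model BMDLs."""
    bmdls = np.asarray(per_model_bmdls, float)
    if len(bmdls) != ws.K:
        raise InvalidModelError("BMDL vector length does not match weights")
    if np.any(~np.isfinite(bmdls) & (ws.weights > 0)):
        raise InvalidModelError("non-finite BMDL with positive weight")
    return float(np.sum(np.where(ws.weights > 0, bmdls, 0.0) * ws.weights))


# ---------------------------------------------------------------------------
# curve averaging


class AveragedCurve:
    """Weighted average of fitted curves, ``f_MA(d) = sum_k w_k f_k(d)``.

    Exposes enough of the fit interface (predict, limits, direction,
    data) for the shared BMD machinery to solve on it numerically."""

    def __init__(self, fits: Sequence[ModelFit], ws: WeightSet):
        if len(fits) != ws.K:
            raise InvalidModelError("number of fits does not match weights")
        dirs = {f.direction for f, w in zip(fits, ws.weights) if w > 0}
        if len(dirs) > 1:
            raise InvalidModelError(
                "cannot average curves with mixed directions (increasing "
                "and decreasing candidates)")
        self.fits = list(fits)
        self.ws = ws
        self.direction = dirs.pop()
        self.data = fits[0].data
        sig = [f.sigma for f in fits if f.sigma is not None]
        self.sigma = float(np.sum([w * s for w, s in
                                   zip(ws.weights, sig)])) if sig else None

    def predict(self, dose):
        vals = [w * f.predict(dose) for f, w in zip(self.fits, self.ws.weights)]
        return np.sum(vals, axis=0)

    def f0(self) -> float:
        return float(sum(w * f.f0() for f, w in zip(self.fits, self.ws.weights)))

    def f_inf(self) -> float:
        return float(sum(w * f.f_inf()
                         for f, w in zip(self.fits, self.ws.weights)))


def ma_curve(fits: Sequence[ModelFit], ws: WeightSet) -> AveragedCurve:
    """Average entire curves; BMD is then solved on the averaged curve
    with backgrounds computed from the averaged curve itself."""
    return AveragedCurve(fits, ws)


def solve_bmd_on_curve(curve: AveragedCurve, spec: BMRSpec) -> float:
    """Brent root search for the BMD on an averaged curve."""
    ystar = _curve_target(curve, spec)
    f0, finf = curve.f0(), curve.f_inf()
    lo_y, hi_y = min(f0, finf), max(f0, finf)
    if not lo_y < ystar < hi_y:
        raise NotReachableError(
            f"BMR not reachable on averaged curve: target {ystar:.6g} "
            f"outside ({lo_y:.6g}, {hi_y:.6g})")
    d_max = float(curve.data.dose.max())
    lo, hi = 1e-12 * d_max, 100.0 * d_max

    def h(logd):
        return float(curve.predict(math.exp(logd))) - ystar

    return float(math.exp(optimize.brentq(h, math.log(lo), math.log(hi),
                                          xtol=1e-13, rtol=1e-14)))


def _curve_target(curve: AveragedCurve, spec: BMRSpec) -> float:
    """Target level with backgrounds taken from the averaged curve."""
    bmr, d = spec.bmr, spec.definition
    inc = (spec.adverse_direction or curve.direction) == "increasing"
    f0 = curve.f0()
    if d in ("additional", "excess"):
        p0 = spec.p0_fixed if spec.background_type == "specified_p0" else f0
        step = bmr if d == "additional" else bmr * (1.0 - p0)
        return p0 + step if inc else p0 - step
    if d in ("hybrid_additional", "hybrid_excess"):
        if curve.sigma is None:
            raise InvalidModelError("hybrid definitions need a continuous fit")
        sigma = curve.sigma
        if spec.background_type == "hybrid_sd":
            x0 = f0 + spec.k_sd * sigma if inc else f0 - spec.k_sd * sigma
            p0 = 1.0 - _norm.cdf(spec.k_sd)
        elif spec.background_type == "absolute_x0":
            x0 = spec.x0
            z = (x0 - f0) / sigma
            p0 = 1.0 - _norm.cdf(z) if inc else _norm.cdf(z)
        else:
            p0 = spec.p0_fixed
            q = _norm.ppf(1.0 - p0) if inc else _norm.ppf(p0)
            x0 = f0 + sigma * q
        step = bmr if d == "hybrid_additional" else bmr * (1.0 - p0)
        tp = p0 + step
        return x0 - sigma * _norm.ppf(1.0 - tp) if inc \
            else x0 - sigma * _norm.ppf(tp)
    if d == "added":
        return f0 + bmr if inc else f0 - bmr
    if d == "extra":
        return f0 + bmr * (curve.f_inf() - f0)
    if d == "relative":
        return f0 * (1.0 + bmr) if inc else f0 * (1.0 - bmr)
    if d == "point":
        return float(bmr)
    raise InvalidModelError(d)  # pragma: no cover


# ---------------------------------------------------------------------------
# bootstrap MA BMDL


def _fit_candidates(data: DoseResponseData, specs, compute_vcov=False):
    fits, kept = [], []
    for s in specs:
        try:
            f = fit_model(data, s, compute_vcov=compute_vcov)
        except (InvalidModelError, ValueError):
            continue
        if f.converged:
            fits.append(f)
            kept.append(s)
    return fits, kept


def ma_bootstrap_bmdl(data: DoseResponseData, specs: Sequence, bmr: BMRSpec,
                      approach: str = "estimate_avg", kind: str = "nonparametric",
                      n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                      scheme: str = "aic", kernel: str = "half_delta"
                      ) -> AveragingResult:
    """Bootstrap MA BMDL; weights are recomputed inside every replicate so
    model-selection uncertainty propagates into the interval."""
    if approach not in ("estimate_avg", "curve_avg"):
        raise InvalidModelError("approach must be 'estimate_avg' or 'curve_avg'")
    specs = [_as_spec(s, data) for s in specs]
    fits, kept = _fit_candidates(data, specs)
    if not fits:
        raise ConvergenceError("no candidate model converged on the data")
    if len(fits) < len(specs):
        warnings.warn(f"{len(specs) - len(fits)} candidate model(s) failed "
                      "on the original data and were excluded")
    crits = [f.aic if scheme == "aic" else f.bic for f in fits]
    ids = [f.spec.family for f in fits]
    ws = compute_weights(crits, scheme=scheme, model_ids=ids, kernel=kernel)
    if approach == "estimate_avg":
        bmds = [solve_bmd(f, bmr).bmd for f in fits]
        bmd_ma = ma_bmd_estimates(bmds, ws)
    else:
        bmd_ma = solve_bmd_on_curve(ma_curve(fits, ws), bmr)

    samples = np.full(n_boot, np.nan)
    needs_fit = kind in ("semiparametric",) or \
        (kind == "parametric" and data.response_kind == "count")
    base_fit = fits[int(np.argmin(crits))] if needs_fit else None
    for r, rng in enumerate(_replicate_rngs(seed, n_boot)):
        try:
            bdata = resample(data, kind, rng, fit=base_fit)
        except InvalidModelError:
            raise
        bfits, _ = _fit_candidates(bdata, kept)
        if not bfits:
            continue
        try:
            bcrits = [f.aic if scheme == "aic" else f.bic for f in bfits]
            bws = compute_weights(bcrits, scheme=scheme,
                                  model_ids=[f.spec.family for f in bfits],
                                  kernel=kernel)
            if approach == "estimate_avg":
                bbmds = [solve_bmd(f, bmr).bmd for f in bfits]
                samples[r] = ma_bmd_estimates(bbmds, bws)
            else:
                samples[r] = solve_bmd_on_curve(ma_curve(bfits, bws), bmr)
        except (InvalidModelError, NotReachableError, ValueError):
            continue
    ok = samples[np.isfinite(samples)]
    n_failed = n_boot - len(ok)
    if n_failed > 0.2 * n_boot:
        raise ConvergenceError(
            f"{n_failed}/{n_boot} MA bootstrap replicates failed")
    bmdl = float(np.quantile(ok, 1.0 - level))
    return AveragingResult(bmd_ma=bmd_ma, bmdl_ma=bmdl, method_bmd=approach,
                           method_bmdl="bootstrap", weights=ws,
                           n_boot=n_boot, n_failed=n_failed, samples=ok)


def _as_spec(s, data: DoseResponseData) -> ModelSpec:
    if isinstance(s, ModelSpec):
        return s
    dist = {"binomial": "binomial", "count": "poisson",
            "continuous": "normal"}[data.response_kind]
    return ModelSpec(family=s, distribution=dist)
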