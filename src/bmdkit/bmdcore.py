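"""Benchmark-dose definitions, background levels and the BMD solver.

The benchmark dose (BMD) is the dose producing a predefined change — the
benchmark response (BMR) — relative to the background response level.
Eight definitions are supported:

========================  =====================================================
``additional``            BMR = f(BMD) - p0                (binomial risk)
``excess``                BMR = (f(BMD) - p0) / (1 - p0)   (binomial risk)
``hybrid_additional``     risk definitions applied to a continuous endpoint
``hybrid_excess``         via the normal-tail probability beyond a cutoff x0
``added``                 BMR = f(BMD) - f(0)              (absolute change)
``extra``                 BMR = (f(BMD)-f(0)) / (f(inf)-f(0))
``relative``              BMR = (f(BMD)-f(0)) / f(0)       (critical effect size)
``point``                 f(BMD) = BMR                     (directly defined)
========================  =====================================================

For decreasing (or decreasing-adverse) curves the signs flip accordingly.
The hybrid approach converts a continuous response to an adverse-event
probability with a cutoff ``x0``, commonly ``k`` standard deviations from
the control mean: ``p0 = 1 - Phi((x0 - f(0))/sigma)`` for an
increasing-adverse endpoint.

The BMD standard error comes from the delta method in an after-fitting
step: the model is fitted once in its natural parameterisation and the
gradient of the BMD with respect to the parameters is obtained from the
implicit-function theorem.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .exceptions import FlatCurveError, InvalidModelError, NotReachableError
from .models import ModelFit

__all__ = [
    "BMRSpec", "Background", "BMDEstimate",
    "background_level", "target_response", "solve_bmd", "bmd_se_delta",
    "default_bmr_spec", "DEFINITION_CODES", "BACKGROUND_CODES",
]

_norm = stats.norm

DEFINITIONS = (
    "additional", "excess", "hybrid_additional", "hybrid_excess",
    "added", "extra", "relative", "point",
)
BACKGROUND_TYPES = ("model_based", "specified_p0", "absolute_x0", "hybrid_sd")

#: R-package-style string codes
DEFINITION_CODES = {
    "additional": "additional", "excess": "excess",
    "hybridAdd": "hybrid_additional", "hybridExc": "hybrid_excess",
    "added": "added", "extra": "extra", "relative": "relative",
    "point": "point",
}
BACKGROUND_CODES = {
    "modelBased": "model_based", "absolute": "absolute_x0",
    "hybridSD": "hybrid_sd", "hybridPercentile": "specified_p0",
}


@dataclass(frozen=True)
class BMRSpec:
    """Benchmark response: its size, definition and background handling.

    ``adverse_direction`` overrides the fitted curve's direction for
    continuous endpoints where the adverse tail is not the direction of
    the trend (``None`` infers it from the fit).
    """

    bmr: float
    definition: str
    background_type: str = "model_based"
    p0_fixed: Optional[float] = None
    x0: Optional[float] = None
    k_sd: Optional[float] = None
    adverse_direction: Optional[str] = None
    sigma_source: str = "pooled"  # pooled residual SD or control-group SD

    def __post_init__(self):
        d = DEFINITION_CODES.get(self.definition, self.definition)
        object.__setattr__(self, "definition", d)
        b = BACKGROUND_CODES.get(self.background_type, self.background_type)
        object.__setattr__(self, "background_type", b)
        if self.definition not in DEFINITIONS:
            raise InvalidModelError(f"unknown BMD definition {self.definition!r}")
        if self.background_type not in BACKGROUND_TYPES:
            raise InvalidModelError(
                f"unknown background type {self.background_type!r}")
        if self.definition != "point" and not self.bmr > 0:
            raise InvalidModelError("BMR must be positive")
        if self.definition in ("additional", "excess", "hybrid_additional",
                               "hybrid_excess") and not self.bmr < 1:
            raise InvalidModelError("risk-type BMR must lie in (0, 1)")
        if self.p0_fixed is not None and not 0.0 <= self.p0_fixed < 1.0:
            raise InvalidModelError("p0 must lie in [0, 1)")

    @property
    def is_hybrid(self) -> bool:
        return self.definition in ("hybrid_additional", "hybrid_excess")


@dataclass(frozen=True)
class Background:
    """Resolved background information for a fit/BMR pair."""

    p0: Optional[float]      # background adverse probability (risk defs)
    f0: float                # background mean response f(0)
    sigma: Optional[float]   # residual SD used by the hybrid approach
    x0: Optional[float]      # adverse cutoff on the response scale
    direction: str           # adverse direction: increasing | decreasing


@dataclass
class BMDEstimate:
    bmd: float
    target_level: float
    definition: str
    se: Optional[float] = None
    p0: Optional[float] = None
    model_id: str = ""
    extrapolated: bool = False


def default_bmr_spec(response_kind: str, convention: str = "efsa") -> BMRSpec:
    """Conventional reporting defaults per response kind.

    Binomial endpoints report a 10% excess risk; continuous endpoints a
    5% relative change (the EFSA critical-effect-size default) or, under
    ``convention="epa"``, the hybrid approach with a one-SD cutoff;
    counts a 10% relative change.
    """
    if response_kind == "binomial":
        return BMRSpec(bmr=0.10, definition="excess")
    if response_kind == "continuous":
        if convention == "epa":
            return BMRSpec(bmr=0.10, definition="hybrid_excess",
                           background_type="hybrid_sd", k_sd=1.0)
        return BMRSpec(bmr=0.05, definition="relative")
    if response_kind == "count":
        return BMRSpec(bmr=0.10, definition="relative")
    raise InvalidModelError(f"unknown response kind {response_kind!r}")


# ---------------------------------------------------------------------------


def _adverse_direction(fit: ModelFit, spec: BMRSpec) -> str:
    if spec.adverse_direction is not None:
        if spec.adverse_direction not in ("increasing", "decreasing"):
            raise InvalidModelError("adverse_direction must be "
                                    "'increasing' or 'decreasing'")
        return spec.adverse_direction
    return fit.direction


def _hybrid_sigma(fit: ModelFit, spec: BMRSpec) -> float:
    if spec.sigma_source == "control":
        data = fit.data
        mask = data.dose == data.dose.min()
        s = float(np.std(data.response[mask], ddof=1))
    else:
        s = fit.sigma
    if s is None or not np.isfinite(s) or s <= 0:
        raise InvalidModelError("hybrid approach needs a finite positive sigma")
    return float(s)


def background_level(fit: ModelFit, spec: BMRSpec) -> Background:
    """Resolve p0 / f(0) / cutoff for a fit under a BMR specification."""
    direction = _adverse_direction(fit, spec)
    f0 = fit.f0()
    binom = fit.spec.distribution == "binomial"

    if spec.is_hybrid:
        if binom:
            raise InvalidModelError("hybrid definitions apply to continuous "
                                    "responses, not binomial fits")
        sigma = _hybrid_sigma(fit, spec)
        if spec.background_type == "absolute_x0":
            if spec.x0 is None:
                raise InvalidModelError("absolute_x0 background requires x0")
            x0 = float(spec.x0)
            z = (x0 - f0) / sigma
            p0 = 1.0 - _norm.cdf(z) if direction == "increasing" else _norm.cdf(z)
        elif spec.background_type == "hybrid_sd":
            if spec.k_sd is None or spec.k_sd <= 0:
                raise InvalidModelError("hybrid_sd background requires k_sd > 0")
            x0 = f0 + spec.k_sd * sigma if direction == "increasing" \
                else f0 - spec.k_sd * sigma
            p0 = 1.0 - _norm.cdf(spec.k_sd)
        elif spec.background_type == "specified_p0":
            if spec.p0_fixed is None:
                raise InvalidModelError("specified_p0 background requires p0_fixed")
            p0 = float(spec.p0_fixed)
            if not 0.0 < p0 < 1.0:
                raise InvalidModelError("hybrid p0 must lie strictly in (0, 1)")
            q = _norm.ppf(1.0 - p0) if direction == "increasing" else _norm.ppf(p0)
            x0 = f0 + sigma * q
        else:
            raise InvalidModelError(
                "hybrid definitions require background_type in "
                "{'absolute_x0', 'hybrid_sd', 'specified_p0'}")
        if not 0.0 < p0 < 1.0:
            raise InvalidModelError(f"background p0 = {p0:.4g} outside (0, 1)")
        return Background(p0=p0, f0=f0, sigma=sigma, x0=x0, direction=direction)

    if spec.definition in ("additional", "excess"):
        if spec.background_type == "specified_p0":
            if spec.p0_fixed is None:
                raise InvalidModelError("specified_p0 background requires p0_fixed")
            p0 = float(spec.p0_fixed)
        elif spec.background_type == "model_based":
            if not binom:
                raise InvalidModelError(
                    "additional/excess risk requires a binomial fit or a "
                    "hybrid background")
            p0 = f0
        else:
            raise InvalidModelError(
                f"background type {spec.background_type!r} not supported for "
                f"{spec.definition!r}")
        if not 0.0 <= p0 < 1.0:
            raise InvalidModelError(f"background p0 = {p0:.4g} outside [0, 1)")
        return Background(p0=p0, f0=f0, sigma=fit.sigma, x0=None,
                          direction=direction)

    # added / extra / relative / point: background is the control mean
    return Background(p0=None, f0=f0, sigma=fit.sigma, x0=None,
                      direction=direction)


def target_response(fit: ModelFit, spec: BMRSpec,
                    bg: Optional[Background] = None) -> float:
    """Response level ``y*`` at which ``f(BMD) = y*`` for the definition."""
    bg = bg if bg is not None else background_level(fit, spec)
    bmr = spec.bmr
    inc = bg.direction == "increasing"
    d = spec.definition

    if d == "additional":
        return bg.p0 + bmr if inc else bg.p0 - bmr
    if d == "excess":
        step = bmr * (1.0 - bg.p0)
        return bg.p0 + step if inc else bg.p0 - step
    if d in ("hybrid_additional", "hybrid_excess"):
        step = bmr if d == "hybrid_additional" else bmr * (1.0 - bg.p0)
        target_p = bg.p0 + step
        if not target_p < 1.0:
            raise NotReachableError(
                f"target adverse probability {target_p:.4g} reaches 1")
        if inc:
            # 1 - Phi((x0 - f)/sigma) = target_p
            return bg.x0 - bg.sigma * _norm.ppf(1.0 - target_p)
        return bg.x0 - bg.sigma * _norm.ppf(target_p)
    if d == "added":
        return bg.f0 + bmr if inc else bg.f0 - bmr
    if d == "extra":
        return bg.f0 + bmr * (fit.f_inf() - bg.f0)
    if d == "relative":
        return bg.f0 * (1.0 + bmr) if inc else bg.f0 * (1.0 - bmr)
    if d == "point":
        return float(bmr)
    raise InvalidModelError(d)  # pragma: no cover


def solve_bmd(fit: ModelFit, spec: BMRSpec, model_id: str = "",
              compute_se: bool = False) -> BMDEstimate:
    """Invert the fitted curve at the target response level.

    Families with an invertible kernel use the closed form; otherwise a
    bracketed Brent search on the log-dose scale over
    ``[1e-12 * d_max, 100 * d_max]``.  Solutions beyond the observed dose
    range are flagged as extrapolated, not refused.
    """
    bg = background_level(fit, spec)
    ystar = target_response(fit, spec, bg)
    bmd = _invert_curve(fit, ystar)
    d_max = float(fit.data.dose.max()) if fit.data is not None else np.inf
    est = BMDEstimate(bmd=bmd, target_level=ystar, definition=spec.definition,
                      p0=bg.p0, model_id=model_id or fit.spec.family,
                      extrapolated=bool(bmd > d_max))
    if compute_se:
        est.se = bmd_se_delta(fit, est, spec=spec)
    return est


def _invert_curve(fit: ModelFit, ystar: float,
                  params: Optional[dict] = None) -> float:
    family = fit.spec.family_obj
    params = params if params is not None else fit.params
    f0 = family.limit0(params)
    finf = family.limit_inf(params)
    lo_y, hi_y = min(f0, finf), max(f0, finf)
    if not (np.isfinite(finf) and np.isfinite(f0)):
        raise NotReachableError("curve has a non-finite asymptote")
    if not lo_y < ystar < hi_y:
        raise NotReachableError(
            f"BMR not reachable: target level {ystar:.6g} outside the fitted "
            f"curve's range ({lo_y:.6g}, {hi_y:.6g})")
    if family.inverse is not None:
        bmd = float(family.inverse(params, ystar))
        if bmd <= 0 or not np.isfinite(bmd):
            raise NotReachableError(f"no positive dose solves the target "
                                    f"level {ystar:.6g}")
        return bmd
    d_max = float(fit.data.dose.max()) if fit.data is not None else 1.0
    lo, hi = 1e-12 * d_max, 100.0 * d_max

    def h(logd):
        return float(family.value(params, math.exp(logd))) - ystar

    ha, hb = h(math.log(lo)), h(math.log(hi))
    if ha * hb > 0:
        raise NotReachableError(
            f"target level {ystar:.6g} not bracketed within "
            f"[{lo:.3g}, {hi:.3g}]")
    return float(math.exp(optimize.brentq(h, math.log(lo), math.log(hi),
                                          xtol=1e-13, rtol=1e-14)))


def bmd_se_delta(fit: ModelFit, est: BMDEstimate, spec: Optional[BMRSpec] = None,
                 vcov: Optional[np.ndarray] = None) -> float:
    """Delta-method SE of the BMD via the implicit-function theorem.

    With ``h(d, beta) = f(d, beta) - y*(beta)`` the gradient is
    ``g = -(dh/dbeta) / (dh/dd)`` at the estimate; ``se = sqrt(g' V g)``.
    ``vcov`` may override the fit's model-based covariance (e.g. with a
    sandwich estimate).
    """
    V = np.asarray(vcov if vcov is not None else fit.vcov, float)
    if not np.all(np.isfinite(V)):
        raise InvalidModelError("covariance matrix is not finite")
    beta = fit.beta
    d0 = est.bmd

    def ystar_at(b):
        if spec is None:
            return est.target_level
        sub = _fit_with_beta(fit, b)
        return target_response(sub, spec)

    def h(d, b):
        return float(fit.mean_at(b, d)) - ystar_at(b)

    # dh/dd by central differences
    hd = d0 * 1e-6 + 1e-12
    dh_dd = (h(d0 + hd, beta) - h(d0 - hd, beta)) / (2 * hd)
    if abs(dh_dd) < 1e-12:
        raise FlatCurveError("curve too flat at the BMD for the delta method")
    g = np.empty(len(beta))
    for j in range(len(beta)):
        hb = 1e-6 * (1.0 + abs(beta[j]))
        bp = beta.copy(); bp[j] += hb
        bm = beta.copy(); bm[j] -= hb
        g[j] = (h(d0, bp) - h(d0, bm)) / (2 * hb)
    g = -g / dh_dd
    var = float(g @ V @ g)
    if var < 0:
        warnings.warn("negative delta-method variance truncated to 0")
        var = 0.0
    return math.sqrt(var)


def _fit_with_beta(fit: ModelFit, beta) -> ModelFit:
    """Shallow copy of a fit with perturbed free parameters."""
    import copy
    sub = copy.copy(fit)
    sub.params = fit.params_at(beta)
    sub.beta = np.asarray(beta, float)
    return sub
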