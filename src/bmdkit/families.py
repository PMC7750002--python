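"""Dose-response curve families.

All sigmoidal families share the drc-style parameterisation built on the
log-dose kernel ``z = b*(log(d) - log(e))``:

* log-logistic   ``f(d) = c + (d_up - c) / (1 + exp(z))``
* log-normal     ``f(d) = c + (d_up - c) * Phi(z)``
* weibull1       ``f(d) = c + (d_up - c) * exp(-exp(z))``
* weibull2       ``f(d) = c + (d_up - c) * (1 - exp(-exp(z)))``

with lower limit ``c``, upper limit ``d_up`` (parameter name ``d``),
slope ``b`` and location ``e > 0``.  Additionally:

* exponential_decay  ``f(x) = c + (d - c) * exp(-x / e)``
* multistage         ``f(x) = c + (1 - c) * (1 - exp(-sum_m b_m x^m))``, b_m >= 0

The value at dose 0 for the log-dose kernels is the analytic limit, never
an evaluation at ``d = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .exceptions import InvalidModelError

__all__ = [
    "Family",
    "get_family",
    "spec_from_code",
    "MODEL_CODES",
]

_norm = stats.norm


def _logit(p):
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# kernel helpers (z = b*(log d - log e))

def _kernel_value(name: str, z):
    if name == "log_logistic":
        return special.expit(-np.asarray(z, float))
    if name == "log_normal":
        return _norm.cdf(z)
    if name == "weibull1":
        return np.exp(-np.exp(z))
    if name == "weibull2":
        return -np.expm1(-np.exp(z))
    raise KeyError(name)


def _kernel_inverse(name: str, k: float) -> float:
    # solves kernel(z) = k for z
    if name == "log_logistic":
        return math.log(1.0 / k - 1.0)
    if name == "log_normal":
        return float(_norm.ppf(k))
    if name == "weibull1":
        return math.log(-math.log(k))
    if name == "weibull2":
        return math.log(-math.log1p(-k))
    raise KeyError(name)


def _kernel_limit0(name: str, b: float) -> float:
    """Kernel limit as d -> 0+ (z -> -inf for b > 0, +inf for b < 0)."""
    z_neg = b > 0  # z -> -inf
    if name == "log_logistic":
        return 1.0 if z_neg else 0.0
    # log_normal, weibull2 CDF-like in z; weibull1 is survival-like
    if name in ("log_normal", "weibull2"):
        return 0.0 if z_neg else 1.0
    if name == "weibull1":
        return 1.0 if z_neg else 0.0
    raise KeyError(name)


@dataclass(frozen=True)
class Family:
    """A dose-response curve family with closed-form limits and inverse."""

    name: str
    param_names: tuple
    value: Callable  # (params: dict, dose: array-like) -> array
    limit0: Callable  # params -> f(0+)
    limit_inf: Callable  # params -> f(inf)
    inverse: Optional[Callable] = None  # (params, y) -> dose, or None
    self_start: Optional[Callable] = None  # (dose, resp) -> params dict

    def __repr__(self):  # pragma: no cover
        return f"Family({self.name})"


# ---------------------------------------------------------------------------
# sigmoidal (log-dose kernel) families

def _make_sigmoid(name: str) -> Family:
    def value(p, dose):
        dose = np.asarray(dose, dtype=float)
        b, c, dup, e = p["b"], p["c"], p["d"], p["e"]
        out = np.empty_like(dose)
        pos = dose > 0
        with np.errstate(divide="ignore", over="ignore"):
            z = b * (np.log(np.where(pos, dose, 1.0)) - math.log(e))
        out[pos] = c + (dup - c) * _kernel_value(name, z[pos])
        out[~pos] = c + (dup - c) * _kernel_limit0(name, b)
        return out if out.ndim else float(out)

    def limit0(p):
        return p["c"] + (p["d"] - p["c"]) * _kernel_limit0(name, p["b"])

    def limit_inf(p):
        return p["c"] + (p["d"] - p["c"]) * (1.0 - _kernel_limit0(name, p["b"]))

    def inverse(p, y):
        b, c, dup, e = p["b"], p["c"], p["d"], p["e"]
        k = (y - c) / (dup - c)
        if not 0.0 < k < 1.0:
            raise InvalidModelError(
                f"target response {y!r} outside the curve range ({c}, {dup})"
            )
        z = _kernel_inverse(name, k)
        return e * math.exp(z / b)

    def self_start(dose, resp):
        return _sigmoid_start(name, dose, resp)

    return Family(name, ("b", "c", "d", "e"), value, limit0, limit_inf,
                  inverse, self_start)


def _sigmoid_start(name: str, dose, resp) -> Dict[str, float]:
    """Initial values: limits from extreme group means, location from the
    dose bracketing the half-range response, slope from a linearised fit."""
    dose = np.asarray(dose, float)
    resp = np.asarray(resp, float)
    levels = np.unique(dose)
    means = np.array([resp[dose == lv].mean() for lv in levels])
    lo, hi = means.min(), means.max()
    rng = max(hi - lo, 1e-8)
    c0 = lo - 0.05 * rng
    d0 = hi + 0.05 * rng
    increasing = means[-1] >= means[0]
    # sign convention making the curve increasing differs per kernel
    bsign = {"log_logistic": -1.0, "log_normal": 1.0,
             "weibull1": -1.0, "weibull2": 1.0}[name]
    if not increasing:
        bsign = -bsign
    k = np.clip((means - c0) / (d0 - c0), 0.02, 0.98)
    nz = levels > 0
    if nz.sum() >= 2:
        u = np.array([_kernel_inverse(name, ki) for ki in k[nz]])
        x = np.log(levels[nz])
        slope, intercept = np.polyfit(x, u, 1)
        if slope * bsign > 0 and abs(slope) > 1e-8:
            b0 = slope
            e0 = math.exp(-intercept / slope)
        else:
            b0, e0 = bsign, _mid_dose(levels, means)
    else:  # pragma: no cover - degenerate designs
        b0, e0 = bsign, _mid_dose(levels, means)
    e0 = min(max(e0, 1e-6), 1e6 * max(levels.max(), 1.0))
    return {"b": float(b0), "c": float(c0), "d": float(d0), "e": float(e0)}


def _mid_dose(levels, means) -> float:
    """Dose bracketing the half-range response, by log-linear interpolation."""
    target = 0.5 * (means.min() + means.max())
    nz = levels > 0
    lv, mn = levels[nz], means[nz]
    if len(lv) == 0:
        return 1.0
    order = np.argsort(lv)
    lv, mn = lv[order], mn[order]
    for i in range(len(lv) - 1):
        a, b = mn[i], mn[i + 1]
        if (a - target) * (b - target) <= 0 and a != b:
            t = (target - a) / (b - a)
            return float(np.exp(np.log(lv[i]) + t * (np.log(lv[i + 1]) - np.log(lv[i]))))
    return float(np.exp(np.mean(np.log(lv))))


# ---------------------------------------------------------------------------
# exponential decay

def _make_exd() -> Family:
    def value(p, dose):
        dose = np.asarray(dose, float)
        out = p["c"] + (p["d"] - p["c"]) * np.exp(-dose / p["e"])
        return out if out.ndim else float(out)

    def inverse(p, y):
        c, d, e = p["c"], p["d"], p["e"]
        k = (y - c) / (d - c)
        if not 0.0 < k <= 1.0:
            raise InvalidModelError(
                f"target response {y!r} outside the curve range ({c}, {d})"
            )
        return -e * math.log(k)

    def self_start(dose, resp):
        dose = np.asarray(dose, float)
        resp = np.asarray(resp, float)
        levels = np.unique(dose)
        means = np.array([resp[dose == lv].mean() for lv in levels])
        d0 = means[0]
        c0 = min(means.min(), d0 - 1e-6) - 0.05 * abs(d0)
        k = np.clip((means - c0) / max(d0 - c0, 1e-8), 1e-3, 1.0)
        slope = np.polyfit(levels, np.log(k), 1)[0]
        e0 = -1.0 / slope if slope < -1e-12 else max(levels.max(), 1.0)
        return {"c": float(c0), "d": float(d0), "e": float(e0)}

    return Family("exponential_decay", ("c", "d", "e"), value,
                  lambda p: p["d"], lambda p: p["c"], inverse, self_start)


# ---------------------------------------------------------------------------
# multistage

def _make_multistage(degree: int) -> Family:
    bnames = tuple(f"b{m}" for m in range(1, degree + 1))

    def poly(p, dose):
        s = np.zeros_like(dose)
        for m, bn in enumerate(bnames, start=1):
            s = s + p[bn] * dose ** m
        return s

    def value(p, dose):
        dose = np.asarray(dose, float)
        out = p["c"] + (1.0 - p["c"]) * (-np.expm1(-poly(p, dose)))
        return out if out.ndim else float(out)

    def inverse(p, y):
        c = p["c"]
        k = (y - c) / (1.0 - c)
        if not 0.0 <= k < 1.0:
            raise InvalidModelError(
                f"target response {y!r} outside the curve range ({c}, 1)"
            )
        target = -math.log1p(-k)
        if degree == 1:
            if p["b1"] <= 0:
                raise InvalidModelError("flat multistage curve has no inverse")
            return target / p["b1"]
        coeffs = [p[bn] for bn in bnames]

        def g(x):
            return sum(bm * x ** m for m, bm in enumerate(coeffs, 1)) - target

        hi = 1.0
        while g(hi) < 0 and hi < 1e12:
            hi *= 2.0
        return float(optimize.brentq(g, 0.0, hi, xtol=1e-14))

    def self_start(dose, resp):
        dose = np.asarray(dose, float)
        resp = np.asarray(resp, float)
        levels = np.unique(dose)
        means = np.array([resp[dose == lv].mean() for lv in levels])
        c0 = float(np.clip(means[0], 1e-4, 0.99))
        k = np.clip((means - c0) / (1.0 - c0), 1e-6, 1.0 - 1e-9)
        y = -np.log1p(-k)
        X = np.column_stack([levels ** m for m in range(1, degree + 1)])
        coef, _ = optimize.nnls(X, y)
        out = {"c": c0}
        for bn, cf in zip(bnames, coef):
            out[bn] = float(max(cf, 1e-9))
        return out

    return Family(f"multistage{degree}", ("c",) + bnames, value,
                  lambda p: p["c"], lambda p: 1.0, inverse, self_start)


# ---------------------------------------------------------------------------
# registry and model-string codes

_FAMILIES: Dict[str, Family] = {
    "log_logistic": _make_sigmoid("log_logistic"),
    "log_normal": _make_sigmoid("log_normal"),
    "weibull1": _make_sigmoid("weibull1"),
    "weibull2": _make_sigmoid("weibull2"),
    "exponential_decay": _make_exd(),
    "multistage1": _make_multistage(1),
    "multistage2": _make_multistage(2),
    "multistage3": _make_multistage(3),
}


def get_family(name: str) -> Family:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise InvalidModelError(
            f"unknown family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None


#: string codes -> (family name, fixed parameters), drc-style
MODEL_CODES: Dict[str, tuple] = {
    "LL.2": ("log_logistic", {"c": 0.0, "d": 1.0}),
    "LL.3": ("log_logistic", {"c": 0.0}),
    "LL.3u": ("log_logistic", {"d": 1.0}),
    "LL.4": ("log_logistic", {}),
    "LN.2": ("log_normal", {"c": 0.0, "d": 1.0}),
    "LN.3": ("log_normal", {"c": 0.0}),
    "LN.3u": ("log_normal", {"d": 1.0}),
    "LN.4": ("log_normal", {}),
    "W1.2": ("weibull1", {"c": 0.0, "d": 1.0}),
    "W1.3": ("weibull1", {"c": 0.0}),
    "W1.4": ("weibull1", {}),
    "W2.2": ("weibull2", {"c": 0.0, "d": 1.0}),
    "W2.3": ("weibull2", {"c": 0.0}),
    "W2.4": ("weibull2", {}),
    "EXD.2": ("exponential_decay", {"c": 0.0}),
    "EXD.3": ("exponential_decay", {}),
    "MS.1": ("multistage1", {}),
    "MS.2": ("multistage2", {}),
    "MS.3": ("multistage3", {}),
}


def spec_from_code(code: str):
    """Return ``(family_name, fixed)`` for a drc-style model code."""
    try:
        fam, fixed = MODEL_CODES[code]
    except KeyError:
        raise InvalidModelError(
            f"unknown model code {code!r}; choose from {sorted(MODEL_CODES)}"
        ) from None
    return fam, dict(fixed)
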