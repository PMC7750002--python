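"""Nonparametric BMD via isotonic regression.

The dose-group mean responses are monotonized with the
pool-adjacent-violators algorithm (PAVA) — the weighted least-squares
projection onto monotone sequences — and the BMD is read off the
resulting step means by linear interpolation on the natural dose scale.
No parametric curve is assumed; uncertainty comes from the shared
bootstrap machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bmdcore import BMDEstimate, BMRSpec
from .data import DoseResponseData
from .exceptions import ConvergenceError, InvalidModelError, NotReachableError
from .uncertainty import BMDLResult, _replicate_rngs, resample

__all__ = ["IsotonicFit", "pava", "bmd_isotonic", "bootstrap_bmd_isotonic"]

_ISO_DEFINITIONS = ("additional", "excess", "added", "extra", "relative",
                    "point")


@dataclass
class IsotonicFit:
    dose_levels: np.ndarray
    fitted_means: np.ndarray
    group_weights: np.ndarray
    direction: str


def pava(means: Sequence[float], weights: Optional[Sequence[float]] = None,
         direction: str = "increasing") -> np.ndarray:
    """Weighted least-squares projection onto monotone sequences.

    Adjacent violating blocks are pooled and replaced by their weighted
    mean until the sequence is monotone in the requested direction.
    """
    y = np.asarray(means, dtype=float)
    if y.size == 0:
        raise InvalidModelError("pava requires a non-empty input")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if len(w) != len(y):
        raise InvalidModelError("means and weights must have equal length")
    if np.any(w <= 0):
        raise InvalidModelError("pava weights must be positive")
    if direction == "decreasing":
        return pava(-y, w, "increasing") * -1.0
    if direction != "increasing":
        raise InvalidModelError("direction must be 'increasing' or 'decreasing'")

    # blocks as (value, weight, count) maintained on a stack
    vals, wts, cnts = [], [], []
    for yi, wi in zip(y, w):
        vals.append(float(yi)); wts.append(float(wi)); cnts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, c2 = vals.pop(), wts.pop(), cnts.pop()
            v1, w1, c1 = vals.pop(), wts.pop(), cnts.pop()
            wt = w1 + w2
            vals.append((v1 * w1 + v2 * w2) / wt)
            wts.append(wt)
            cnts.append(c1 + c2)
    out = np.empty_like(y)
    i = 0
    for v, c in zip(vals, cnts):
        out[i:i + c] = v
        i += c
    return out


def _infer_direction(data: DoseResponseData) -> str:
    """Sign of the weighted Spearman correlation between dose and response."""
    levels, means, sizes = data.group_means()
    rd = stats.rankdata(levels)
    rm = stats.rankdata(means)
    w = sizes / sizes.sum()
    md, mm = np.sum(w * rd), np.sum(w * rm)
    cov = np.sum(w * (rd - md) * (rm - mm))
    if cov == 0:
        raise InvalidModelError(
            "no monotone trend detected; pass an explicit direction")
    return "increasing" if cov > 0 else "decreasing"


def isotonic_fit(data: DoseResponseData,
                 direction: Optional[str] = None) -> IsotonicFit:
    direction = direction or _infer_direction(data)
    levels, means, sizes = data.group_means()
    fitted = pava(means, sizes, direction)
    return IsotonicFit(dose_levels=levels, fitted_means=fitted,
                       group_weights=sizes, direction=direction)


def bmd_isotonic(data: DoseResponseData, bmr: BMRSpec,
                 direction: Optional[str] = None) -> BMDEstimate:
    """BMD from the monotonized dose-group means by linear interpolation.

    Backgrounds come from the monotonized control mean; hybrid
    definitions (which need a parametric residual SD) are not supported.
    """
    if bmr.definition not in _ISO_DEFINITIONS:
        raise InvalidModelError(
            f"isotonic BMD supports definitions {_ISO_DEFINITIONS}")
    iso = isotonic_fit(data, direction)
    f0 = iso.fitted_means[0]
    fend = iso.fitted_means[-1]
    inc = iso.direction == "increasing"
    b = bmr.bmr
    d = bmr.definition
    if d == "additional":
        p0 = bmr.p0_fixed if bmr.background_type == "specified_p0" else f0
        ystar = p0 + b if inc else p0 - b
    elif d == "excess":
        p0 = bmr.p0_fixed if bmr.background_type == "specified_p0" else f0
        ystar = p0 + b * (1 - p0) if inc else p0 - b * (1 - p0)
    elif d == "added":
        ystar = f0 + b if inc else f0 - b
    elif d == "extra":
        ystar = f0 + b * (fend - f0)
    elif d == "relative":
        ystar = f0 * (1 + b) if inc else f0 * (1 - b)
    else:  # point
        ystar = float(b)

    lo, hi = min(f0, fend), max(f0, fend)
    if not lo <= ystar <= hi:
        raise NotReachableError(
            f"BMR not reachable: target {ystar:.6g} outside the monotonized "
            f"range ({lo:.6g}, {hi:.6g})")
    bmd = _interpolate(iso.dose_levels, iso.fitted_means, ystar, inc)
    return BMDEstimate(bmd=bmd, target_level=float(ystar),
                       definition=bmr.definition,
                       p0=None, model_id="isotonic")


def _interpolate(doses, means, ystar, increasing) -> float:
    """First dose at which the monotone step means reach ``ystar``."""
    sgn = 1.0 if increasing else -1.0
    m = sgn * np.asarray(means)
    t = sgn * ystar
    for i in range(len(m)):
        if m[i] >= t:
            if i == 0:
                return float(doses[0])
            if m[i] == m[i - 1]:
                return float(doses[i - 1])
            frac = (t - m[i - 1]) / (m[i] - m[i - 1])
            return float(doses[i - 1] + frac * (doses[i] - doses[i - 1]))
    return float(doses[-1])  # pragma: no cover - guarded by range check


def bootstrap_bmd_isotonic(data: DoseResponseData, bmr: BMRSpec,
                           n_boot: int = 1000, level: float = 0.95,
                           seed: int = 0,
                           direction: Optional[str] = None) -> BMDLResult:
    """Nonparametric bootstrap BMDL for the isotonic BMD."""
    direction = direction or _infer_direction(data)
    samples = np.full(n_boot, np.nan)
    for r, rng in enumerate(_replicate_rngs(seed, n_boot)):
        try:
            bdata = resample(data, "nonparametric", rng)
            samples[r] = bmd_isotonic(bdata, bmr, direction=direction).bmd
        except (InvalidModelError, NotReachableError):
            continue
    ok = samples[np.isfinite(samples)]
    n_failed = n_boot - len(ok)
    if n_failed > 0.2 * n_boot:
        raise ConvergenceError(
            f"{n_failed}/{n_boot} isotonic bootstrap replicates failed")
    return BMDLResult(bmdl=float(np.quantile(ok, 1.0 - level)),
                      method="boot_isotonic", level=level, n_boot=n_boot,
                      n_failed=n_failed, samples=ok)
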