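"""Two-step meta-analytic BMD for hierarchical (nested) designs.

Observations from sub-experiments are correlated, so a single pooled
dose-response fit understates uncertainty.  The two-step alternative
fits the dose-response model separately within each cluster, extracts
the per-cluster BMD and its delta-method SE, and combines them with a
DerSimonian-Laird random-effects model.  The combination can be done on
the natural BMD scale (default) or on log-BMD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from .bmdcore import BMRSpec, solve_bmd
from .data import DoseResponseData
from .exceptions import ConvergenceError, DataError, InvalidModelError, NotReachableError
from .models import ModelSpec, fit_model

__all__ = ["MetaInput", "MetaResult", "fit_per_cluster", "meta_combine",
           "bmd_hierarchical"]

_norm = stats.norm


@dataclass
class MetaInput:
    estimates: np.ndarray
    ses: np.ndarray
    cluster_ids: List

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, float)
        self.ses = np.asarray(self.ses, float)
        if len(self.estimates) != len(self.ses):
            raise InvalidModelError("estimates and ses must have equal length")
        if np.any(self.ses <= 0) or not np.all(np.isfinite(self.ses)):
            raise InvalidModelError("per-cluster SEs must be positive and finite")

    @property
    def K(self) -> int:
        return len(self.estimates)


@dataclass
class MetaResult:
    bmd_combined: float
    se_combined: float
    bmdl_combined: float
    tau2: float
    Q: float
    K: int
    scale: str = "natural"


def fit_per_cluster(data: DoseResponseData, spec, bmr: BMRSpec) -> MetaInput:
    """Fit the dose-response model within each cluster and extract the
    per-cluster BMD with its delta-method SE.  Clusters that fail to
    converge (or where the BMR is unreachable) are excluded with a
    warning."""
    if data.cluster is None:
        raise DataError("hierarchical analysis requires a cluster column")
    est, ses, ids, dropped = [], [], [], []
    for label, sub in data.clusters():
        try:
            fit = fit_model(sub, spec)
            if not fit.converged:
                raise ConvergenceError("no convergence")
            e = solve_bmd(fit, bmr, compute_se=True)
            if not (np.isfinite(e.bmd) and np.isfinite(e.se) and e.se > 0):
                raise InvalidModelError("degenerate BMD or SE")
        except (InvalidModelError, NotReachableError, ConvergenceError,
                DataError, ValueError):
            dropped.append(label)
            continue
        est.append(e.bmd)
        ses.append(e.se)
        ids.append(label)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} cluster(s) without a usable "
                      f"fit: {dropped}")
    if len(est) < 2:
        raise ConvergenceError(
            f"fewer than 2 usable clusters ({len(est)}) for meta-analysis")
    return MetaInput(estimates=np.array(est), ses=np.array(ses),
                     cluster_ids=ids)


def meta_combine(m: MetaInput, level: float = 0.95,
                 scale: str = "natural") -> MetaResult:
    """DerSimonian-Laird random-effects combination.

    ``tau2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w))`` with fixed
    weights ``w_i = 1/se_i^2``; the combined estimate uses weights
    ``1/(se_i^2 + tau2)``.  ``scale='log'`` combines log-BMDs (delta-method
    SEs ``se_i / bmd_i``) and exponentiates back.
    """
    if m.K == 1:
        warnings.warn("single cluster: pass-through, no heterogeneity estimate")
        theta, se = float(m.estimates[0]), float(m.ses[0])
        bmdl = max(0.0, theta - _norm.ppf(level) * se)
        return MetaResult(theta, se, bmdl, 0.0, 0.0, 1, scale)
    if scale == "log":
        if np.any(m.estimates <= 0):
            raise InvalidModelError("log-scale combination needs positive BMDs")
        theta_i = np.log(m.estimates)
        se_i = m.ses / m.estimates
    elif scale == "natural":
        theta_i, se_i = m.estimates, m.ses
    else:
        raise InvalidModelError("scale must be 'natural' or 'log'")

    w = 1.0 / se_i ** 2
    theta_fe = np.sum(w * theta_i) / np.sum(w)
    Q = float(np.sum(w * (theta_i - theta_fe) ** 2))
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - (m.K - 1)) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (se_i ** 2 + tau2)
    theta_re = float(np.sum(wstar * theta_i) / np.sum(wstar))
    se_re = math.sqrt(1.0 / np.sum(wstar))
    z = _norm.ppf(level)
    if scale == "log":
        bmd = math.exp(theta_re)
        bmdl = math.exp(theta_re - z * se_re)
        se_out = bmd * se_re  # back-transformed delta-method SE
        return MetaResult(bmd, se_out, bmdl, tau2, Q, m.K, scale)
    bmdl = max(0.0, theta_re - z * se_re)
    return MetaResult(theta_re, se_re, bmdl, tau2, Q, m.K, scale)


def bmd_hierarchical(data: DoseResponseData, spec, bmr: BMRSpec,
                     level: float = 0.95, scale: str = "natural") -> MetaResult:
    """Convenience wrapper: per-cluster fits then DL combination."""
    return meta_combine(fit_per_cluster(data, spec, bmr), level=level,
                        scale=scale)
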