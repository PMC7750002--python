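"""BMDL estimation: Wald/delta intervals, inverse regression, bootstrap
resampling schemes, and sandwich (robust) covariance.

The BMDL is the lower limit of a one-sided confidence interval for the
BMD (default level 0.95).  Bootstrap BMDLs are the empirical 5% quantile
(type-7) of the replicate BMD distribution; binomial parametric
resampling applies the shrinkage rule ``(Y + 1/4) / (N + 1/2)`` to dose
groups with only events or only non-events so that resampling does not
degenerate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .bmdcore import BMDEstimate, BMRSpec, bmd_se_delta, solve_bmd, target_response, background_level
from .data import DoseResponseData
from .exceptions import ConvergenceError, InvalidModelError, NotReachableError
from .models import ModelFit, ModelSpec, fit_model, numeric_hessian

__all__ = [
    "BMDLResult", "SandwichParts", "bmdl_delta", "bmdl_inverse_regression",
    "shrink_binomial", "bootstrap_bmd", "resample", "sandwich_vcov",
    "BMDL_METHOD_CODES",
]

_norm = stats.norm

BMDL_METHOD_CODES = {
    "delta": "delta", "inv": "inverse_regression",
    "bootNP": "boot_nonparametric", "bootPar": "boot_parametric",
    "bootSemi": "boot_semiparametric",
}

MAX_FAILURE_FRACTION = 0.2


@dataclass
class BMDLResult:
    bmdl: float
    method: str
    level: float = 0.95
    n_boot: int = 0
    n_failed: int = 0
    samples: Optional[np.ndarray] = None


@dataclass
class SandwichParts:
    A: np.ndarray               # observed information
    B: np.ndarray               # score outer-product sum
    vcov_sandwich: np.ndarray   # A^-1 B A^-T


# ---------------------------------------------------------------------------
# Wald / delta


def bmdl_delta(fit: ModelFit, est: BMDEstimate, level: float = 0.95,
               scale: str = "natural") -> BMDLResult:
    """One-sided Wald lower limit; natural scale truncates at 0, the log
    scale guarantees positivity."""
    if est.se is None or not np.isfinite(est.se):
        raise InvalidModelError("delta BMDL requires a finite BMD standard error")
    z = _norm.ppf(level)
    if est.se == 0:
        warnings.warn("zero BMD standard error; BMDL equals BMD")
        return BMDLResult(bmdl=est.bmd, method="delta", level=level)
    if scale == "natural":
        bmdl = max(0.0, est.bmd - z * est.se)
        return BMDLResult(bmdl=bmdl, method="delta", level=level)
    if scale == "log":
        se_log = est.se / est.bmd
        return BMDLResult(bmdl=est.bmd * math.exp(-z * se_log),
                          method="delta_log", level=level)
    raise InvalidModelError("scale must be 'natural' or 'log'")


# ---------------------------------------------------------------------------
# inverse regression


def bmdl_inverse_regression(fit: ModelFit, spec: BMRSpec, level: float = 0.95,
                            vcov: Optional[np.ndarray] = None) -> BMDLResult:
    """BMDL as the smallest dose whose one-sided pointwise confidence limit
    for the predicted response reaches the target level."""
    V = np.asarray(vcov if vcov is not None else fit.vcov, float)
    bg = background_level(fit, spec)
    ystar = target_response(fit, spec, bg)
    est = solve_bmd(fit, spec)
    z = _norm.ppf(level)
    sign = 1.0 if bg.direction == "increasing" else -1.0
    beta = fit.beta

    def band(d):
        g = np.empty(len(beta))
        for j in range(len(beta)):
            h = 1e-6 * (1.0 + abs(beta[j]))
            bp = beta.copy(); bp[j] += h
            bm = beta.copy(); bm[j] -= h
            g[j] = (float(fit.mean_at(bp, d)) - float(fit.mean_at(bm, d))) / (2 * h)
        se = math.sqrt(max(float(g @ V @ g), 0.0))
        return float(fit.predict(d)) + sign * z * se

    def gfun(d):
        return sign * (band(d) - ystar)

    g_bmd = gfun(est.bmd)
    if g_bmd < 0:  # numerically flat band; cannot pass below its own curve
        return BMDLResult(bmdl=est.bmd, method="inverse_regression", level=level)
    lo = min(est.bmd * 1e-8, 1e-10)
    if gfun(lo) >= 0:
        # band already beyond target at a negligible dose: truncate at 0
        return BMDLResult(bmdl=0.0, method="inverse_regression", level=level)
    bmdl = float(optimize.brentq(gfun, lo, est.bmd, xtol=1e-12, rtol=1e-12))
    return BMDLResult(bmdl=bmdl, method="inverse_regression", level=level)


# ---------------------------------------------------------------------------
# bootstrap


def shrink_binomial(events: float, trials: float) -> float:
    """Shrunken resampling proportion ``(Y + 1/4) / (N + 1/2)`` for dose
    groups consisting of only events or only non-events."""
    return (events + 0.25) / (trials + 0.5)


def resample(data: DoseResponseData, kind: str, rng: np.random.Generator,
             fit: Optional[ModelFit] = None,
             sd_source: str = "pooled") -> DoseResponseData:
    """One bootstrap resample of ``data``.

    * ``nonparametric`` — resampling with replacement within each dose
      group (grouped binomial rows draw Binom(N_i, Y_i/N_i));
    * ``parametric`` — binomial draws with shrunken proportions for
      degenerate groups; normal draws with dose-group means and a common
      SD; count draws from the fitted Poisson/NB model;
    * ``semiparametric`` — fitted values plus recentred resampled
      residuals (continuous only).
    """
    kind_map = {"bootNP": "nonparametric", "bootPar": "parametric",
                "bootSemi": "semiparametric"}
    kind = kind_map.get(kind, kind)
    rk = data.response_kind
    out = data.to_frame().copy()

    if rk == "binomial":
        p_obs = data.events / data.trials
        if kind == "nonparametric":
            p = p_obs
        elif kind == "parametric":
            p = np.where((data.events == 0) | (data.events == data.trials),
                         shrink_binomial(data.events, data.trials), p_obs)
        else:
            raise InvalidModelError(
                "semiparametric bootstrap applies to continuous data only")
        out["events"] = rng.binomial(data.trials.astype(int), p)
        return DoseResponseData(dose=data.dose, response_kind="binomial",
                                events=out["events"].to_numpy(),
                                trials=data.trials, weight=data.weight,
                                cluster=data.cluster)

    y = data.response
    new = np.empty_like(y, dtype=float)
    if kind == "nonparametric":
        for lv in np.unique(data.dose):
            m = data.dose == lv
            idx = np.flatnonzero(m)
            new[m] = y[rng.choice(idx, size=idx.size, replace=True)]
    elif kind == "parametric":
        if rk == "continuous":
            levels = np.unique(data.dose)
            means = {lv: y[data.dose == lv].mean() for lv in levels}
            if sd_source == "control":
                sd = float(np.std(y[data.dose == data.dose.min()], ddof=1))
            else:
                dev = np.concatenate([y[data.dose == lv] - means[lv]
                                      for lv in levels])
                sd = float(np.sqrt(np.sum(dev ** 2) /
                                   max(len(y) - len(levels), 1)))
            mu = np.array([means[d] for d in data.dose])
            new = rng.normal(mu, sd)
        else:  # count
            if fit is None:
                raise InvalidModelError(
                    "parametric count bootstrap needs a fitted model")
            mu = fit.predict(data.dose)
            if fit.spec.exposure_as_offset and data.weight is not None:
                mu = mu * data.weight
            if fit.spec.distribution == "negbin":
                th = fit.theta
                new = rng.negative_binomial(th, th / (th + mu))
            else:
                new = rng.poisson(mu)
    elif kind == "semiparametric":
        if rk != "continuous":
            raise InvalidModelError(
                "semiparametric bootstrap applies to continuous data only")
        if fit is None:
            raise InvalidModelError("semiparametric bootstrap needs a fitted model")
        mu = fit.predict(data.dose)
        resid = y - mu
        resid = resid - resid.mean()  # recentre for exchangeability
        new = mu + rng.choice(resid, size=len(resid), replace=True)
    else:
        raise InvalidModelError(f"unknown bootstrap kind {kind!r}")
    return DoseResponseData(dose=data.dose, response_kind=rk, response=new,
                            weight=data.weight, cluster=data.cluster)


def _replicate_rngs(seed: int, n_boot: int):
    """Independent per-replicate substreams from one seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_boot)]


def bootstrap_bmd(data: DoseResponseData, spec, bmr: BMRSpec,
                  kind: str = "nonparametric", n_boot: int = 1000,
                  level: float = 0.95, seed: int = 0,
                  sd_source: str = "pooled") -> BMDLResult:
    """Bootstrap BMDL: resample, refit (self-started), re-solve the BMD;
    the BMDL is the (1 - level) empirical quantile of converged
    replicates.  More than 20% failed replicates aborts."""
    if n_boot < 50:
        raise InvalidModelError("n_boot must be at least 50")
    kind = {"bootNP": "nonparametric", "bootPar": "parametric",
            "bootSemi": "semiparametric"}.get(kind, kind)
    if kind == "semiparametric" and data.response_kind != "continuous":
        raise InvalidModelError(
            "semiparametric bootstrap applies to continuous data only")
    if isinstance(spec, ModelSpec):
        mspec = spec
    else:
        dist = {"binomial": "binomial", "count": "poisson",
                "continuous": "normal"}[data.response_kind]
        mspec = ModelSpec(family=spec, distribution=dist)
    needs_fit = (kind == "semiparametric" or
                 (kind == "parametric" and data.response_kind == "count"))
    base_fit = fit_model(data, mspec, compute_vcov=False) if needs_fit else None
    samples = np.full(n_boot, np.nan)
    for r, rng in enumerate(_replicate_rngs(seed, n_boot)):
        try:
            bdata = resample(data, kind, rng,
                             fit=base_fit if needs_fit else None,
                             sd_source=sd_source)
            bfit = fit_model(bdata, mspec, compute_vcov=False)
            if not bfit.converged:
                continue
            samples[r] = solve_bmd(bfit, bmr).bmd
        except (InvalidModelError, NotReachableError, ValueError):
            continue
    ok = samples[np.isfinite(samples)]
    n_failed = n_boot - len(ok)
    if n_failed > MAX_FAILURE_FRACTION * n_boot:
        raise ConvergenceError(
            f"{n_failed}/{n_boot} bootstrap replicates failed; review the "
            "model and data before trusting a bootstrap BMDL")
    bmdl = float(np.quantile(ok, 1.0 - level))  # type-7 empirical quantile
    return BMDLResult(bmdl=bmdl, method=f"boot_{kind}", level=level,
                      n_boot=n_boot, n_failed=n_failed, samples=ok)


# ---------------------------------------------------------------------------
# sandwich covariance


def _per_obs_loglik(fit: ModelFit, data: DoseResponseData):
    """Vector of per-observation log-likelihood contributions as a
    function of the free curve parameters (natural scale)."""
    spec = fit.spec
    dist = spec.distribution
    dose = data.dose

    if dist == "binomial":
        y, n = data.events, data.trials

        def ll(beta):
            mu = np.clip(fit.mean_at(beta, dose), 1e-10, 1 - 1e-10)
            return y * np.log(mu) + (n - y) * np.log1p(-mu)

    elif dist == "normal":
        y = np.log(data.response) if spec.log_transform_response else data.response
        s2 = fit.sigma ** 2

        def ll(beta):
            mu = fit.mean_at(beta, dose)
            return -0.5 * (y - mu) ** 2 / s2

    else:
        y = data.response
        expo = (data.weight if (spec.exposure_as_offset and data.weight is not None)
                else np.ones(len(y)))
        if dist == "poisson":
            def ll(beta):
                mu = np.clip(expo * fit.mean_at(beta, dose), 1e-12, None)
                return y * np.log(mu) - mu
        else:
            th = fit.theta

            def ll(beta):
                mu = np.clip(expo * fit.mean_at(beta, dose), 1e-12, None)
                return y * np.log(mu) - (y + th) * np.log(mu + th)
    return ll


def sandwich_vcov(fit: ModelFit, data: Optional[DoseResponseData] = None,
                  cluster_robust: bool = False) -> SandwichParts:
    """Robust covariance ``A^-1 B A^-T`` with A the observed information
    and B the outer-product sum of per-observation (or per-cluster) score
    vectors.  Point estimates are untouched; only SEs change."""
    data = data if data is not None else fit.data
    ll = _per_obs_loglik(fit, data)
    beta = fit.beta
    p = len(beta)
    nrow = len(ll(beta))
    scores = np.empty((nrow, p))
    for j in range(p):
        h = 1e-6 * (1.0 + abs(beta[j]))
        bp = beta.copy(); bp[j] += h
        bm = beta.copy(); bm[j] -= h
        scores[:, j] = (ll(bp) - ll(bm)) / (2 * h)
    if cluster_robust:
        if data.cluster is None:
            raise InvalidModelError("cluster-robust sandwich needs a cluster column")
        import pandas as pd
        labels = pd.unique(data.cluster)
        S = np.vstack([scores[data.cluster == lab].sum(axis=0) for lab in labels])
    else:
        S = scores
    B = S.T @ S

    def total_nll(b):
        return -float(np.sum(ll(b)))

    A = numeric_hessian(total_nll, beta)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise InvalidModelError("singular observed information matrix")
    V = Ainv @ B @ Ainv.T
    V = 0.5 * (V + V.T)
    return SandwichParts(A=A, B=B, vcov_sandwich=V)
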