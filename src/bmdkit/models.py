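"""Maximum-likelihood dose-response model fitting.

Four response distributions are supported: normal (continuous, with a
single pooled residual SD profiled out of the likelihood), binomial
(grouped events/trials rows), Poisson and negative binomial (NB2,
variance ``mu + mu^2/theta``) for counts, the latter two optionally with
the observation weight entering as a multiplicative exposure
(log-offset).  The optimizer is a derivative-free simplex refined by
quasi-Newton, with the location parameter kept positive through a log
transform; the covariance of the estimates is the inverse observed
information (numeric Hessian).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .data import DoseResponseData
from .exceptions import ConvergenceError, DataError, InvalidModelError
from .families import Family, get_family, spec_from_code

__all__ = [
    "ModelSpec", "ModelFit", "fit_model", "predict_response",
    "information_criteria", "standardized_residuals", "overdispersion_ratio",
    "numeric_hessian",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which curve family and response distribution to fit.

    ``family`` can also be given as a drc-style string code ("LL.3",
    "W1.4", "EXD.2", ...), in which case the code's conventional fixed
    parameters are merged into ``fixed``.
    """

    family: str
    distribution: str = "normal"  # normal | binomial | poisson | negbin
    fixed: Dict[str, float] = field(default_factory=dict)
    log_transform_response: bool = False
    exposure_as_offset: bool = False

    def __post_init__(self):
        fam, code_fixed = (self.family, {})
        if self.family in _CODE_CACHE or "." in self.family:
            fam, code_fixed = spec_from_code(self.family)
        merged = {**code_fixed, **self.fixed}
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "fixed", merged)
        family = get_family(fam)
        unknown = set(merged) - set(family.param_names)
        if unknown:
            raise InvalidModelError(
                f"fixed parameters {sorted(unknown)} not in family "
                f"{fam!r} (has {family.param_names})"
            )
        if self.distribution not in ("normal", "binomial", "poisson", "negbin"):
            raise InvalidModelError(f"unknown distribution {self.distribution!r}")

    @property
    def family_obj(self) -> Family:
        return get_family(self.family)

    @property
    def free_names(self):
        return tuple(n for n in self.family_obj.param_names if n not in self.fixed)


from .families import MODEL_CODES as _CODE_CACHE  # noqa: E402  (cycle-free)


@dataclass
class ModelFit:
    """A fitted dose-response curve and its likelihood summaries."""

    spec: ModelSpec
    params: Dict[str, float]           # all curve parameters, incl. fixed
    beta: np.ndarray                   # free parameter estimates
    free_names: tuple
    vcov: np.ndarray                   # covariance of beta (model-based)
    loglik: float
    aic: float
    bic: float
    residual_deviance: float
    df_residual: int
    n_obs: int
    converged: bool
    sigma: Optional[float] = None      # residual SD (continuous)
    theta: Optional[float] = None      # NB2 dispersion
    direction: str = "increasing"
    data: Optional[DoseResponseData] = None
    message: str = ""

    # ------------------------------------------------------------------
    @property
    def n_free(self) -> int:
        """Free parameters counted in AIC (curve + sigma or theta)."""
        k = len(self.free_names)
        if self.spec.distribution == "normal":
            k += 1
        elif self.spec.distribution == "negbin":
            k += 1
        return k

    def predict(self, dose):
        return self.spec.family_obj.value(self.params, dose)

    def f0(self) -> float:
        return float(self.spec.family_obj.limit0(self.params))

    def f_inf(self) -> float:
        return float(self.spec.family_obj.limit_inf(self.params))

    def params_at(self, beta: Sequence[float]) -> Dict[str, float]:
        p = dict(self.spec.fixed)
        for name, val in zip(self.free_names, beta):
            p[name] = float(val)
        return p

    def mean_at(self, beta, dose):
        return self.spec.family_obj.value(self.params_at(beta), dose)


def predict_response(fit: ModelFit, dose) -> float:
    """Fitted mean response at ``dose`` (analytic limit at dose 0)."""
    if not fit.converged:
        raise InvalidModelError("cannot predict from a non-converged fit")
    if not np.all(np.isfinite(fit.beta)):
        raise InvalidModelError("fit has non-finite parameters")
    if np.any(np.asarray(dose, float) < 0):
        raise InvalidModelError("dose must be non-negative")
    return fit.predict(dose)


# ---------------------------------------------------------------------------
# likelihood builders



def _fast_mean_fn(fam_name, family, dose):
    """Specialized mean function with the dose-dependent work precomputed."""
    from .families import _kernel_limit0, _kernel_value
    dose = np.asarray(dose, float)
    if fam_name in ("log_logistic", "log_normal", "weibull1", "weibull2"):
        pos = dose > 0
        logd = np.log(dose[pos])
        all_pos = bool(pos.all())
        n = len(dose)
        neg = ~pos

        def mean_fn(p):
            b, c, dup, e = p["b"], p["c"], p["d"], p["e"]
            k = _kernel_value(fam_name, b * (logd - math.log(e)))
            if all_pos:
                return c + (dup - c) * k
            out = np.empty(n)
            out[pos] = c + (dup - c) * k
            out[neg] = c + (dup - c) * _kernel_limit0(fam_name, b)
            return out

        return mean_fn
    if fam_name == "exponential_decay":
        def mean_fn(p):
            return p["c"] + (p["d"] - p["c"]) * np.exp(-dose / p["e"])

        return mean_fn
    return lambda p: family.value(p, dose)


def _nll_builder(data: DoseResponseData, spec: ModelSpec):
    """Return (nll(theta_vec), unpack, names) for the free parameters.

    ``theta_vec`` stacks the free curve parameters (location ``e`` on the
    log scale) plus ``log(theta)`` for the negative binomial.
    """
    family = spec.family_obj
    fixed = spec.fixed
    free = [n for n in family.param_names if n not in fixed]
    log_scaled = [n in ("e",) for n in free]
    dose = data.dose
    dist = spec.distribution

    def unpack(vec):
        p = dict(fixed)
        for name, is_log, v in zip(free, log_scaled, vec[: len(free)]):
            # clamp log-scale parameters so simplex excursions cannot overflow
            p[name] = math.exp(min(max(v, -500.0), 500.0)) if is_log \
                else float(v)
        return p

    def pack(p: Dict[str, float]):
        out = [math.log(p[n]) if is_log else p[n]
               for n, is_log in zip(free, log_scaled)]
        return np.array(out, dtype=float)

    mean_fn = _fast_mean_fn(spec.family, family, dose)

    if dist == "binomial":
        y, n = data.events, data.trials
        lgam = (special.gammaln(n + 1) - special.gammaln(y + 1)
                - special.gammaln(n - y + 1)).sum()

        def nll(vec):
            p = unpack(vec)
            mu = np.clip(mean_fn(p), 1e-10, 1.0 - 1e-10)
            return -(lgam + np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu)))

    elif dist == "normal":
        y = np.log(data.response) if spec.log_transform_response else data.response
        w = data.weight if data.weight is not None else np.ones(len(y))
        nobs = len(y)

        def nll(vec):
            mu = mean_fn(unpack(vec))
            rss = np.sum(w * (y - mu) ** 2)
            if not np.isfinite(rss) or rss <= 0:
                rss = max(rss, 1e-300)
            # profiled sigma^2 = rss/n
            return 0.5 * nobs * (_LOG2PI + math.log(rss / nobs) + 1.0) \
                - 0.5 * np.sum(np.log(w))

    elif dist in ("poisson", "negbin"):
        y = data.response
        expo = (data.weight if (spec.exposure_as_offset and data.weight is not None)
                else np.ones(len(y)))
        lfact = special.gammaln(y + 1).sum()

        if dist == "poisson":
            def nll(vec):
                mu = np.clip(expo * mean_fn(unpack(vec)), 1e-12, None)
                return -(np.sum(y * np.log(mu) - mu) - lfact)
        else:
            def nll(vec):
                mu = np.clip(expo * mean_fn(unpack(vec)), 1e-12, None)
                th = math.exp(vec[-1])
                ll = (special.gammaln(y + th) - special.gammaln(th)
                      - special.gammaln(y + 1)
                      + th * math.log(th) + y * np.log(mu)
                      - (y + th) * np.log(mu + th))
                return -np.sum(ll)
    else:  # pragma: no cover
        raise InvalidModelError(dist)

    # multistage slope coefficients must stay non-negative
    ms_idx = [i for i, nme in enumerate(free) if nme.startswith("b") and
              spec.family.startswith("multistage")]
    if ms_idx:
        base = nll

        def nll(vec):  # noqa: F811
            if any(vec[i] < 0 for i in ms_idx):
                return 1e10 + 1e10 * sum(-vec[i] for i in ms_idx if vec[i] < 0)
            return base(vec)

    return nll, unpack, pack, free


def _saturated_loglik(data: DoseResponseData, spec: ModelSpec) -> float:
    """Log-likelihood of the saturated (one mean per row/group) model."""
    dist = spec.distribution
    if dist == "binomial":
        y, n = data.events, data.trials
        p = y / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(p), 0.0)
            t2 = np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
        lgam = (special.gammaln(n + 1) - special.gammaln(y + 1)
                - special.gammaln(n - y + 1)).sum()
        return float(lgam + np.sum(t1 + t2))
    if dist == "poisson":
        y = data.response
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y) - y, 0.0)
        return float(np.sum(t) - special.gammaln(y + 1).sum())
    return np.nan  # deviance reported via RSS for normal; negbin n/a


# ---------------------------------------------------------------------------


def numeric_hessian(fun, x, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                fpp = fun(x + ei); fmm = fun(x - ei)
                H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
            else:
                fpp = fun(x + ei + ej); fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej); fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _vcov_from_hessian(H: np.ndarray) -> np.ndarray:
    try:
        vc = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vc = np.linalg.pinv(H)
        warnings.warn("singular observed information; using pseudo-inverse")
    # enforce symmetry
    return 0.5 * (vc + vc.T)


def fit_model(data: DoseResponseData, spec, start: Optional[Dict[str, float]] = None,
              compute_vcov: bool = True) -> ModelFit:
    """Fit a dose-response model by maximum likelihood.

    ``spec`` may be a :class:`ModelSpec` or a drc-style string code, in
    which case the distribution is chosen from the data's response kind.
    Self-starter initial values are used when ``start`` is absent.
    Non-convergence yields a flagged fit (``converged=False``), never a
    silent one.
    """
    if isinstance(spec, str):
        dist = {"binomial": "binomial", "count": "poisson",
                "continuous": "normal"}[data.response_kind]
        spec = ModelSpec(family=spec, distribution=dist)
    _check_compat(data, spec)

    family = spec.family_obj
    n_free_curve = len(spec.free_names)
    if data.n_dose_levels < n_free_curve:
        raise DataError(
            f"need at least {n_free_curve} distinct dose levels for "
            f"{spec.family} ({data.n_dose_levels} found)"
        )
    if data.n_dose_levels == n_free_curve:
        warnings.warn("as many dose levels as free parameters: saturated mean fit")

    nll, unpack, pack, free = _nll_builder(data, spec)

    # --- starting values ------------------------------------------------
    yv = data.yvalues
    if spec.distribution == "normal" and spec.log_transform_response:
        yv = np.log(yv)
    if start is None:
        start_params = family.self_start(data.dose, yv)
        start_params.update(spec.fixed)
    else:
        start_params = {**family.self_start(data.dose, yv), **start, **spec.fixed}
    if spec.distribution == "binomial":
        for nme in ("c", "d"):
            if nme in start_params and nme not in spec.fixed:
                start_params[nme] = float(np.clip(start_params[nme], 1e-4, 1 - 1e-4))
    x0 = pack(start_params)
    if spec.distribution == "negbin":
        mu0 = np.maximum(family.value(start_params, data.dose), 1e-8)
        resp = data.response
        excess = max(np.mean((resp - mu0) ** 2 - mu0), 1e-8)
        theta0 = float(np.clip(np.mean(mu0 ** 2) / excess, 0.05, 100.0))
        x0 = np.append(x0, math.log(theta0))

    # --- optimize: simplex then quasi-Newton polish ---------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        best = res
        polish_ok = False
        if compute_vcov:
            # quasi-Newton refinement where the Hessian will be taken
            res2 = optimize.minimize(nll, res.x, method="BFGS",
                                     options={"gtol": 1e-7, "maxiter": 200})
            if res2.fun <= res.fun:
                best = res2
                polish_ok = res2.success
    converged = bool(np.isfinite(best.fun)) and (res.success or polish_ok)

    xhat = best.x
    params = unpack(xhat)
    # report beta on the natural scale
    beta = np.array([params[nme] for nme in free])
    loglik = -float(best.fun)

    # --- summaries ------------------------------------------------------
    n_obs = len(data)
    sigma = theta = None
    if spec.distribution == "normal":
        y = np.log(data.response) if spec.log_transform_response else data.response
        w = data.weight if data.weight is not None else np.ones(n_obs)
        mu = family.value(params, data.dose)
        rss = float(np.sum(w * (y - mu) ** 2))
        sigma = math.sqrt(max(rss, 0.0) / n_obs)
        residual_deviance = rss
        df_residual = n_obs - n_free_curve
        if not converged and sigma <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
            converged = True  # perfect interpolation: likelihood diverges
    elif spec.distribution == "negbin":
        theta = math.exp(xhat[-1])
        residual_deviance = np.nan
        df_residual = n_obs - n_free_curve - 1
    else:
        sat = _saturated_loglik(data, spec)
        residual_deviance = 2.0 * (sat - loglik)
        df_residual = n_obs - n_free_curve

    k = n_free_curve + (1 if spec.distribution in ("normal", "negbin") else 0)
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n_obs) - 2.0 * loglik

    # --- covariance on the natural scale --------------------------------
    if compute_vcov:
        def nll_natural(b):
            p = dict(spec.fixed)
            p.update(zip(free, b))
            vec = pack(p)
            if spec.distribution == "negbin":
                vec = np.append(vec, xhat[-1])
            return nll(vec)

        if spec.distribution == "negbin":
            def nll_full(b):
                p = dict(spec.fixed)
                p.update(zip(free, b[:-1]))
                return nll(np.append(pack(p), b[-1]))
            H = numeric_hessian(nll_full, np.append(beta, xhat[-1]))
            vcov_full = _vcov_from_hessian(H)
            vcov = vcov_full[: len(free), : len(free)]
        else:
            H = numeric_hessian(nll_natural, beta)
            vcov = _vcov_from_hessian(H)
    else:
        vcov = np.full((len(free), len(free)), np.nan)

    f0 = family.limit0(params)
    fmax = family.value(params, float(data.dose.max())) if len(data) else f0
    direction = "increasing" if fmax >= f0 else "decreasing"

    return ModelFit(
        spec=spec, params=params, beta=beta, free_names=tuple(free),
        vcov=np.asarray(vcov, float), loglik=loglik, aic=aic, bic=bic,
        residual_deviance=float(residual_deviance), df_residual=int(df_residual),
        n_obs=n_obs, converged=converged, sigma=sigma, theta=theta,
        direction=direction, data=data, message=str(best.get("message", "")),
    )


def _check_compat(data: DoseResponseData, spec: ModelSpec):
    ok = {
        "binomial": ("binomial",),
        "poisson": ("count",),
        "negbin": ("count",),
        "normal": ("continuous", "count"),
    }[spec.distribution]
    if data.response_kind not in ok:
        raise DataError(
            f"distribution {spec.distribution!r} is incompatible with "
            f"{data.response_kind!r} response data"
        )


# ---------------------------------------------------------------------------
# diagnostics


def information_criteria(fit: ModelFit):
    """(AIC, BIC); the parameter count includes sigma / theta."""
    if not fit.converged:
        raise InvalidModelError("information criteria require a converged fit")
    return fit.aic, fit.bic


def standardized_residuals(fit: ModelFit, data: Optional[DoseResponseData] = None):
    """Residuals scaled by the model's predicted standard deviation."""
    if not fit.converged:
        raise InvalidModelError("residuals require a converged fit")
    data = data if data is not None else fit.data
    dist = fit.spec.distribution
    mu = fit.predict(data.dose)
    if dist == "normal":
        y = np.log(data.response) if fit.spec.log_transform_response else data.response
        scale = np.full(len(y), fit.sigma)
    elif dist == "binomial":
        y = data.events / data.trials
        scale = np.sqrt(mu * (1.0 - mu) / data.trials)
    else:
        y = data.response
        if fit.spec.exposure_as_offset and data.weight is not None:
            mu = mu * data.weight
        scale = np.sqrt(mu) if dist == "poisson" else np.sqrt(mu + mu ** 2 / fit.theta)
    zero = scale <= 0
    if np.any(zero):
        warnings.warn("zero predicted variance; residual reported as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero, 0.0, (y - mu) / np.where(zero, 1.0, scale))
    return r


def overdispersion_ratio(fit: ModelFit) -> float:
    """Residual deviance / residual df; values above 1 flag overdispersion."""
    if fit.spec.distribution not in ("binomial", "poisson"):
        raise InvalidModelError(
            "overdispersion ratio is defined for binomial/poisson fits"
        )
    if fit.df_residual == 0:
        raise InvalidModelError("zero residual degrees of freedom")
    return fit.residual_deviance / fit.df_residual
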