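"""Seeded synthetic dose-response generators.

Every test input of the package is generated here, without downloads.
The continuous validation design mirrors a four-parameter log-logistic
truth with lower and upper limits 2 and 10 at doses
(0.1, 0.5, 1, 5, 10) under normal noise with SD 1 or 0.1 and 10 or 3
replicates per dose; location and shape are set to e = 2, b = 1 (a
documented choice — only the limits and design are prescribed by the
validation blueprint this emulates).

Each generated dataset carries a truth record that can compute the true
BMD for any supported definition by plain bisection at tolerance 1e-12 —
an algorithm deliberately different from the package solver's closed
forms and Brent search, so the two never confirm each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .bmdcore import BMRSpec
from .data import DoseResponseData
from .exceptions import DataError, InvalidModelError
from .families import get_family

__all__ = ["ScenarioSpec", "Truth", "generate", "make_fixture_suite",
           "write_fixture_suite", "validation_scenario"]

_norm = stats.norm


@dataclass(frozen=True)
class ScenarioSpec:
    family: str
    params: Dict[str, float]
    doses: Tuple[float, ...]
    replicates: int = 10
    noise: str = "normal"          # normal | binomial | poisson | negbin
    sd: Optional[float] = None     # normal noise SD
    trials: int = 50               # binomial group size
    theta: Optional[float] = None  # NB2 dispersion
    n_clusters: Optional[int] = None
    between_cluster_sd: float = 0.0   # SD of log-location across clusters
    seed: int = 0

    def __post_init__(self):
        if any(d < 0 for d in self.doses):
            raise DataError("doses must be non-negative")
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")
        if self.noise == "normal" and (self.sd is None or self.sd < 0):
            raise DataError("normal noise requires sd >= 0")
        if self.noise == "negbin" and (self.theta is None or self.theta <= 0):
            raise DataError("negbin noise requires theta > 0")


@dataclass
class Truth:
    """Generating curve plus an independent true-BMD oracle."""

    family: str
    params: Dict[str, float]
    sd: Optional[float] = None
    theta: Optional[float] = None

    def curve(self, dose):
        return get_family(self.family).value(self.params, dose)

    def f0(self) -> float:
        return float(get_family(self.family).limit0(self.params))

    def f_inf(self) -> float:
        return float(get_family(self.family).limit_inf(self.params))

    def direction(self) -> str:
        return "increasing" if self.f_inf() >= self.f0() else "decreasing"

    # -- independent oracle: definition algebra + bisection -------------
    def target_level(self, bmr: BMRSpec) -> float:
        b, d = bmr.bmr, bmr.definition
        f0 = self.f0()
        inc = (bmr.adverse_direction or self.direction()) == "increasing"
        if d in ("additional", "excess"):
            p0 = bmr.p0_fixed if bmr.background_type == "specified_p0" else f0
            step = b if d == "additional" else b * (1 - p0)
            return p0 + step if inc else p0 - step
        if d in ("hybrid_additional", "hybrid_excess"):
            sigma = self.sd
            if sigma is None or sigma <= 0:
                raise InvalidModelError("hybrid truth needs a normal-noise sd")
            if bmr.background_type == "hybrid_sd":
                x0 = f0 + bmr.k_sd * sigma if inc else f0 - bmr.k_sd * sigma
                p0 = 1.0 - _norm.cdf(bmr.k_sd)
            elif bmr.background_type == "absolute_x0":
                x0 = bmr.x0
                z = (x0 - f0) / sigma
                p0 = 1.0 - _norm.cdf(z) if inc else _norm.cdf(z)
            else:
                p0 = bmr.p0_fixed
                q = _norm.ppf(1 - p0) if inc else _norm.ppf(p0)
                x0 = f0 + sigma * q
            step = b if d == "hybrid_additional" else b * (1 - p0)
            tp = p0 + step
            return x0 - sigma * _norm.ppf(1 - tp) if inc \
                else x0 - sigma * _norm.ppf(tp)
        if d == "added":
            return f0 + b if inc else f0 - b
        if d == "extra":
            return f0 + b * (self.f_inf() - f0)
        if d == "relative":
            return f0 * (1 + b) if inc else f0 * (1 - b)
        if d == "point":
            return float(b)
        raise InvalidModelError(d)

    def true_bmd(self, bmr: BMRSpec, hi: float = 1e8) -> float:
        """Bisection on [0, hi] at tolerance 1e-12 (relative)."""
        ystar = self.target_level(bmr)
        f0, finf = self.f0(), self.f_inf()
        if not min(f0, finf) < ystar < max(f0, finf):
            raise InvalidModelError(
                f"true target {ystar:.6g} outside curve range")
        sgn = 1.0 if finf > f0 else -1.0

        def g(x):
            return sgn * (float(self.curve(x)) - ystar)

        lo, high = 0.0, 1.0
        while g(high) < 0:
            high *= 2.0
            if high > hi:
                raise InvalidModelError("true BMD bracket exceeded")
        for _ in range(200):
            mid = 0.5 * (lo + high)
            if g(mid) < 0:
                lo = mid
            else:
                high = mid
            if high - lo <= 1e-12 * max(1.0, high):
                break
        return 0.5 * (lo + high)


def generate(spec: ScenarioSpec,
             seed: Optional[int] = None) -> Tuple[DoseResponseData, Truth]:
    """Generate one dataset (deterministic under the seed) plus its truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    family = get_family(spec.family)
    truth = Truth(family=spec.family, params=dict(spec.params), sd=spec.sd,
                  theta=spec.theta)

    if spec.n_clusters:
        doses, resp, events, trials, clusters = [], [], [], [], []
        for c in range(spec.n_clusters):
            cp = dict(spec.params)
            if spec.between_cluster_sd > 0:
                cp["e"] = cp["e"] * math.exp(
                    rng.normal(0.0, spec.between_cluster_sd))
            sub = _generate_flat(spec, cp, rng)
            doses.append(sub.dose)
            clusters.append(np.full(len(sub), f"c{c + 1}"))
            if spec.noise == "binomial":
                events.append(sub.events); trials.append(sub.trials)
            else:
                resp.append(sub.response)
        kw = dict(dose=np.concatenate(doses),
                  cluster=np.concatenate(clusters))
        if spec.noise == "binomial":
            data = DoseResponseData(response_kind="binomial",
                                    events=np.concatenate(events),
                                    trials=np.concatenate(trials), **kw)
        else:
            kind = "continuous" if spec.noise == "normal" else "count"
            data = DoseResponseData(response_kind=kind,
                                    response=np.concatenate(resp), **kw)
        return data, truth
    return _generate_flat(spec, spec.params, rng), truth


def _generate_flat(spec: ScenarioSpec, params, rng) -> DoseResponseData:
    family = get_family(spec.family)
    doses = np.repeat(np.asarray(spec.doses, float), spec.replicates)
    mu = family.value(params, doses)
    if spec.noise == "binomial":
        if np.any((mu < 0) | (mu > 1)):
            raise DataError("binomial mean outside [0, 1] at some dose")
        levels = np.asarray(spec.doses, float)
        pmu = family.value(params, levels)
        events = rng.binomial(spec.trials, pmu)
        return DoseResponseData(dose=levels, response_kind="binomial",
                                events=events,
                                trials=np.full(len(levels), spec.trials))
    if spec.noise == "normal":
        y = mu + rng.normal(0.0, spec.sd, size=len(doses)) if spec.sd > 0 \
            else mu.copy()
        return DoseResponseData(dose=doses, response_kind="continuous",
                                response=y)
    if spec.noise == "poisson":
        return DoseResponseData(dose=doses, response_kind="count",
                                response=rng.poisson(np.maximum(mu, 0.0)))
    if spec.noise == "negbin":
        th = spec.theta
        m = np.maximum(mu, 1e-12)
        return DoseResponseData(dose=doses, response_kind="count",
                                response=rng.negative_binomial(th, th / (th + m)))
    raise DataError(f"unknown noise kind {spec.noise!r}")


def validation_scenario(sd: float = 0.1, replicates: int = 10,
                        seed: int = 0) -> ScenarioSpec:
    """The continuous validation design: LL4 truth with limits 2 and 10 at
    doses (0.1, 0.5, 1, 5, 10)."""
    return ScenarioSpec(
        family="log_logistic",
        params={"b": 1.0, "c": 2.0, "d": 10.0, "e": 2.0},
        doses=(0.1, 0.5, 1.0, 5.0, 10.0),
        replicates=replicates, noise="normal", sd=sd, seed=seed,
    )


# ---------------------------------------------------------------------------
# canonical fixture suite


def make_fixture_suite(seed: int = 0) -> Dict[str, Tuple[DoseResponseData, Truth]]:
    """The canonical named test datasets, regenerated deterministically."""
    ss = np.random.SeedSequence(seed).spawn(5)
    out: Dict[str, Tuple[DoseResponseData, Truth]] = {}

    # binomial data lying exactly on an LL2 curve with b=-1, e=10
    exact = DoseResponseData(
        dose=np.array([10.0 / 9.0, 10.0, 90.0]),
        response_kind="binomial",
        events=np.array([10.0, 50.0, 90.0]),
        trials=np.array([100.0, 100.0, 100.0]))
    out["exact_binomial"] = (
        exact, Truth("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0}))

    # earthworm-style quantal test: natural mortality 0.10 as lower limit
    worm = ScenarioSpec(
        family="log_normal",
        params={"b": 2.2, "c": 0.10, "d": 1.0, "e": 45.0},
        doses=(0.0, 10.0, 20.0, 40.0, 80.0, 160.0),
        noise="binomial", trials=40,
        seed=int(ss[0].generate_state(1)[0] % 2 ** 31))
    out["earthworm_like"] = generate(worm)

    # overdispersed shoot counts, decreasing log-logistic mean
    counts = ScenarioSpec(
        family="log_logistic",
        params={"b": 1.0, "c": 0.0, "d": 20.0, "e": 1.0},
        doses=(0.0, 0.01, 0.1, 1.0, 10.0, 100.0), replicates=6,
        noise="negbin", theta=1.0,
        seed=int(ss[1].generate_state(1)[0] % 2 ** 31))
    out["count_overdispersed"] = generate(counts)

    # fish-style continuous decline, four-candidate averaging target
    fish = ScenarioSpec(
        family="exponential_decay",
        params={"c": 0.0, "d": 10.0, "e": 80.0},
        doses=(0.0, 3.1, 6.3, 12.5, 25.0, 50.0, 100.0), replicates=10,
        noise="normal", sd=1.0,
        seed=int(ss[2].generate_state(1)[0] % 2 ** 31))
    out["fish_like"] = generate(fish)

    # nine-cluster hierarchical quantal design
    hier = ScenarioSpec(
        family="log_logistic",
        params={"b": -2.0, "c": 0.0, "d": 1.0, "e": 0.1},
        doses=(0.0, 0.025, 0.05, 0.1, 0.2, 0.4), noise="binomial",
        trials=20, n_clusters=9, between_cluster_sd=0.3,
        seed=int(ss[3].generate_state(1)[0] % 2 ** 31))
    out["hierarchical_9"] = generate(hier)
    return out


def write_fixture_suite(directory, seed: int = 0) -> Dict[str, str]:
    """Write the fixture suite as CSV files with JSON truth sidecars."""
    import os
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, (data, truth) in make_fixture_suite(seed).items():
        csv_path = os.path.join(directory, f"{name}.csv")
        data.to_frame().to_csv(csv_path, index=False)
        side = {"family": truth.family, "params": truth.params,
                "sd": truth.sd, "theta": truth.theta}
        with open(os.path.join(directory, f"{name}.json"), "w") as fh:
            json.dump(side, fh, indent=1)
        paths[name] = csv_path
    return paths
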