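"""BMD definitions, backgrounds, solver and delta-method SE."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

import bmdkit as bk
from bmdkit.bmdcore import background_level, solve_bmd, target_response
from bmdkit.exceptions import InvalidModelError, NotReachableError

from conftest import make_fit


class TestBackgroundLevel:
    def test_model_based_p0_is_lower_limit(self):
        """A quantal fit with estimated natural mortality 0.10 as its
        lower limit has background risk p0 = 0.10."""
        fit = make_fit("log_normal", {"b": 2.0, "c": 0.10, "d": 1.0, "e": 30.0},
                       fixed={"d": 1.0})
        spec = bk.BMRSpec(bmr=0.05, definition="additional")
        bg = background_level(fit, spec)
        assert bg.p0 == pytest.approx(0.10, abs=1e-12)

    def test_hybrid_sd_two_sigma_background(self):
        """Cutoff two SDs above the control mean: p0 = 1 - Phi(2)."""
        fit = make_fit("log_logistic",
                       {"b": -1.0, "c": 1.0, "d": 5.0, "e": 10.0},
                       distribution="normal", sigma=0.5)
        spec = bk.BMRSpec(bmr=0.05, definition="hybridAdd",
                          background_type="hybridSD", k_sd=2.0)
        bg = background_level(fit, spec)
        assert bg.p0 == pytest.approx(1.0 - stats.norm.cdf(2.0), abs=1e-10)
        assert bg.p0 == pytest.approx(0.02275, abs=5e-6)
        assert bg.x0 == pytest.approx(1.0 + 2.0 * 0.5)

    def test_specified_p0_passthrough(self):
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        spec = bk.BMRSpec(bmr=0.05, definition="excess",
                          background_type="specified_p0", p0_fixed=0.0)
        assert background_level(fit, spec).p0 == 0.0

    def test_hybrid_on_binomial_rejected(self):
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        spec = bk.BMRSpec(bmr=0.05, definition="hybridAdd",
                          background_type="hybridSD", k_sd=1.0)
        with pytest.raises(InvalidModelError, match="binomial"):
            background_level(fit, spec)


class TestTargetResponse:
    def test_additional_risk_worked_example(self):
        """Background mortality 0.10 plus BMR 0.05 targets 0.15 dead."""
        fit = make_fit("log_normal", {"b": 2.0, "c": 0.10, "d": 1.0, "e": 30.0},
                       fixed={"d": 1.0})
        spec = bk.BMRSpec(bmr=0.05, definition="additional",
                          background_type="specified_p0", p0_fixed=0.10)
        assert target_response(fit, spec) == pytest.approx(0.15, abs=1e-12)

    def test_excess_risk_worked_example(self):
        """Excess risk rescales by the survivors: 0.05*0.9 + 0.10 = 0.145."""
        fit = make_fit("log_normal", {"b": 2.0, "c": 0.10, "d": 1.0, "e": 30.0},
                       fixed={"d": 1.0})
        spec = bk.BMRSpec(bmr=0.05, definition="excess",
                          background_type="specified_p0", p0_fixed=0.10)
        assert target_response(fit, spec) == pytest.approx(0.145, abs=1e-12)

    def test_relative_decreasing(self):
        fit = make_fit("exponential_decay", {"c": 0.0, "d": 8.0, "e": 5.0},
                       distribution="normal", sigma=0.5)
        spec = bk.BMRSpec(bmr=0.1, definition="relative")
        assert target_response(fit, spec) == pytest.approx(7.2, abs=1e-12)

    def test_hybrid_sd_target_algebra(self):
        """k=2 cutoff, BMR 0.05 additional: target mean is
        f(0) + sigma*(2 - Phi^-1(1 - 0.05 - p0)) with p0 = 1 - Phi(2)."""
        f0, sigma = 3.0, 0.4
        fit = make_fit("log_logistic",
                       {"b": -1.0, "c": f0, "d": 9.0, "e": 10.0},
                       distribution="normal", sigma=sigma)
        spec = bk.BMRSpec(bmr=0.05, definition="hybridAdd",
                          background_type="hybridSD", k_sd=2.0)
        p0 = 1.0 - stats.norm.cdf(2.0)
        expect = f0 + sigma * (2.0 - stats.norm.ppf(1.0 - 0.05 - p0))
        assert target_response(fit, spec) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(f0 + 0.545 * sigma, abs=1e-3 * sigma)

    def test_unreachable_bmr_names_range(self):
        fit = make_fit("log_logistic",
                       {"b": -1.0, "c": 0.0, "d": 0.3, "e": 10.0},
                       fixed={"c": 0.0})
        spec = bk.BMRSpec(bmr=0.5, definition="excess")
        with pytest.raises(NotReachableError, match="range"):
            solve_bmd(fit, spec)


class TestSolveBmd:
    def test_ll2_excess_closed_form(self):
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        spec = bk.BMRSpec(bmr=0.1, definition="excess",
                          background_type="specified_p0", p0_fixed=0.0)
        est = solve_bmd(fit, spec)
        # closed form: d/(d+10) = 0.1  =>  d = 10/9; bisection agrees
        assert est.bmd == pytest.approx(10.0 / 9.0, abs=1e-8)

        def g(d):
            return float(fit.predict(d)) - 0.1
        lo, hi = 1e-6, 100.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if g(mid) < 0 else (lo, mid)
        assert est.bmd == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_point_definition_at_half_is_location(self):
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        est = solve_bmd(fit, bk.BMRSpec(bmr=0.5, definition="point"))
        assert est.bmd == pytest.approx(10.0, rel=1e-10)

    def test_definition_consistency(self, validation_fit):
        """f(BMD) equals the target level to 1e-8 for every definition."""
        data, truth, fit = validation_fit
        specs = [
            bk.BMRSpec(bmr=0.05, definition="relative"),
            bk.BMRSpec(bmr=0.5, definition="added"),
            bk.BMRSpec(bmr=0.1, definition="extra"),
            bk.BMRSpec(bmr=0.05, definition="hybridExc",
                       background_type="hybridSD", k_sd=2.0),
            bk.BMRSpec(bmr=5.0, definition="point"),
        ]
        for spec in specs:
            est = solve_bmd(fit, spec)
            assert float(fit.predict(est.bmd)) == pytest.approx(
                est.target_level, abs=1e-8)

    def test_bmd_monotone_in_bmr(self, exact_ll2_fit):
        bmds = [solve_bmd(exact_ll2_fit,
                          bk.BMRSpec(bmr=b, definition="excess")).bmd
                for b in np.linspace(0.01, 0.2, 15)]
        assert np.all(np.diff(bmds) > 0)

    def test_additional_equals_excess_at_zero_background(self):
        for b, e in [(-0.5, 2.0), (-1.0, 10.0), (-2.0, 0.3), (-1.3, 40.0)]:
            fit = make_fit("log_logistic", {"b": b, "c": 0.0, "d": 1.0, "e": e},
                           fixed={"c": 0.0, "d": 1.0})
            b1 = solve_bmd(fit, bk.BMRSpec(bmr=0.07, definition="additional")).bmd
            b2 = solve_bmd(fit, bk.BMRSpec(bmr=0.07, definition="excess")).bmd
            assert abs(b1 - b2) < 1e-8

    def test_extra_equals_excess_at_unit_limits(self):
        for b, e in [(0.7, 5.0), (1.5, 12.0)]:
            fit = make_fit("weibull2", {"b": b, "c": 0.0, "d": 1.0, "e": e},
                           fixed={"c": 0.0, "d": 1.0})
            b1 = solve_bmd(fit, bk.BMRSpec(bmr=0.1, definition="extra")).bmd
            b2 = solve_bmd(fit, bk.BMRSpec(bmr=0.1, definition="excess")).bmd
            assert abs(b1 - b2) < 1e-8


def test_default_bmr_conventions():
    from bmdkit.bmdcore import default_bmr_spec
    assert default_bmr_spec("binomial").definition == "excess"
    assert default_bmr_spec("binomial").bmr == 0.10
    assert default_bmr_spec("continuous").definition == "relative"
    assert default_bmr_spec("continuous").bmr == 0.05
    epa = default_bmr_spec("continuous", convention="epa")
    assert epa.background_type == "hybrid_sd" and epa.k_sd == 1.0
    assert default_bmr_spec("count").definition == "relative"


class TestDeltaSE:
    def test_zero_covariance_gives_zero_se(self, exact_ll2_fit):
        spec = bk.BMRSpec(bmr=0.1, definition="excess")
        est = solve_bmd(exact_ll2_fit, spec)
        se = bk.bmd_se_delta(exact_ll2_fit, est, spec=spec,
                             vcov=np.zeros((2, 2)))
        assert se == 0.0

    def test_se_matches_reparameterized_model(self):
        """Oracle: refit the LL2 model parameterized directly in
        (b, log BMD); its Wald SE for BMD must agree within 10%."""
        spec = bk.ScenarioSpec(family="log_logistic",
                               params={"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                               doses=(0.0, 1.25, 2.5, 5.0, 10.0, 20.0),
                               noise="binomial", trials=200, seed=17)
        data, truth = bk.generate(spec)
        fit = bk.fit_model(data, "LL.2")
        bspec = bk.BMRSpec(bmr=0.1, definition="excess",
                           background_type="specified_p0", p0_fixed=0.0)
        est = solve_bmd(fit, bspec, compute_se=True)

        # reparameterization: e = bmd * exp(-z*/b), z* = logit(1 - bmr)
        zstar = math.log(1.0 / 0.1 - 1.0)
        y, n, dose = data.events, data.trials, data.dose
        pos = dose > 0

        def nll(x):
            b, logbmd = x
            e = math.exp(logbmd) * math.exp(-zstar / b)
            mu = np.zeros(len(dose))
            z = b * (np.log(dose[pos]) - math.log(e))
            mu[pos] = 1.0 / (1.0 + np.exp(z))
            mu[~pos] = 0.0 if b < 0 else 1.0
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            return -np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu))

        res = optimize.minimize(nll, np.array([-1.0, math.log(est.bmd)]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        from bmdkit.models import numeric_hessian
        H = numeric_hessian(nll, res.x)
        v_logbmd = np.linalg.inv(H)[1, 1]
        bmd_hat = math.exp(res.x[1])
        se_oracle = bmd_hat * math.sqrt(v_logbmd)  # delta back-transform
        assert est.bmd == pytest.approx(bmd_hat, rel=1e-4)
        assert est.se == pytest.approx(se_oracle, rel=0.10)

    def test_se_stable_under_solver_tolerance(self, exact_ll2_fit):
        spec = bk.BMRSpec(bmr=0.1, definition="excess")
        est = solve_bmd(exact_ll2_fit, spec, compute_se=True)
        est2 = solve_bmd(exact_ll2_fit, spec)
        est2.bmd = est2.bmd * (1 + 1e-10)  # re-solve perturbation
        se2 = bk.bmd_se_delta(exact_ll2_fit, est2, spec=spec)
        assert abs(se2 - est.se) / est.se < 1e-4
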