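"""BMDL methods: Wald, inverse regression, bootstrap, sandwich."""

import numpy as np
import pytest
from scipy import stats

import bmdkit as bk
from bmdkit.bmdcore import solve_bmd
from bmdkit.exceptions import ConvergenceError, InvalidModelError
from bmdkit.uncertainty import (bmdl_delta, bmdl_inverse_regression,
                                bootstrap_bmd, resample, sandwich_vcov,
                                shrink_binomial)
from bmdkit.bmdcore import BMDEstimate

from conftest import make_fit


class TestWaldBmdl:
    def test_arithmetic(self):
        est = BMDEstimate(bmd=10.0, target_level=0.1, definition="excess",
                          se=2.0)
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        res = bmdl_delta(fit, est, level=0.95)
        assert res.bmdl == pytest.approx(10.0 - stats.norm.ppf(0.95) * 2.0,
                                         abs=1e-10)
        assert res.bmdl == pytest.approx(6.710, abs=5e-4)

    def test_truncation_vs_log_scale(self):
        est = BMDEstimate(bmd=1.0, target_level=0.1, definition="excess",
                          se=5.0)
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        assert bmdl_delta(fit, est).bmdl == 0.0
        assert bmdl_delta(fit, est, scale="log").bmdl > 0.0

    def test_zero_se_warns_and_returns_bmd(self):
        est = BMDEstimate(bmd=3.0, target_level=0.1, definition="excess",
                          se=0.0)
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        with pytest.warns(UserWarning, match="zero"):
            assert bmdl_delta(fit, est).bmdl == 3.0

    def test_strictly_decreasing_in_level(self):
        est = BMDEstimate(bmd=10.0, target_level=0.1, definition="excess",
                          se=2.0)
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        levels = [0.8, 0.9, 0.95, 0.99]
        out = [bmdl_delta(fit, est, level=l).bmdl for l in levels]
        assert np.all(np.diff(out) < 0)


class TestInverseRegression:
    def test_zero_covariance_band_equals_curve(self):
        fit = make_fit("log_logistic", {"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                       fixed={"c": 0.0, "d": 1.0})
        spec = bk.BMRSpec(bmr=0.1, definition="excess",
                          background_type="specified_p0", p0_fixed=0.0)
        res = bmdl_inverse_regression(fit, spec)
        assert res.bmdl == pytest.approx(solve_bmd(fit, spec).bmd, rel=1e-6)

    def test_below_bmd_with_positive_covariance(self, exact_ll2_fit):
        spec = bk.BMRSpec(bmr=0.1, definition="excess")
        res = bmdl_inverse_regression(exact_ll2_fit, spec)
        assert 0 < res.bmdl < solve_bmd(exact_ll2_fit, spec).bmd

    def test_asymptotic_agreement_with_delta(self):
        spec = bk.ScenarioSpec(family="log_logistic",
                               params={"b": -1.0, "c": 0.0, "d": 1.0, "e": 10.0},
                               doses=(0.0, 1.25, 2.5, 5.0, 10.0, 20.0),
                               noise="binomial", trials=500, seed=29)
        data, _ = bk.generate(spec)
        fit = bk.fit_model(data, "LL.2")
        bspec = bk.BMRSpec(bmr=0.1, definition="excess",
                           background_type="specified_p0", p0_fixed=0.0)
        est = solve_bmd(fit, bspec, compute_se=True)
        d = bmdl_delta(fit, est).bmdl
        i = bmdl_inverse_regression(fit, bspec).bmdl
        assert abs(i - d) / d < 0.25


class TestShrinkage:
    def test_formula_values(self):
        assert shrink_binomial(0, 40) == pytest.approx(0.25 / 40.5, abs=1e-12)
        assert shrink_binomial(0, 40) == pytest.approx(0.006173, abs=1e-6)
        assert shrink_binomial(20, 20) == pytest.approx(20.25 / 20.5, abs=1e-12)
        assert shrink_binomial(20, 20) == pytest.approx(0.98780, abs=1e-5)

    def test_applied_only_to_degenerate_groups(self):
        data = bk.DoseResponseData(dose=[0.0, 1.0, 2.0],
                                   response_kind="binomial",
                                   events=[0, 10, 40], trials=[40, 40, 40])
        rng = np.random.default_rng(0)
        draws = np.array([resample(data, "parametric", rng).events
                          for _ in range(4000)])
        # degenerate group resamples above zero sometimes, shrunken rate
        assert draws[:, 0].mean() / 40 == pytest.approx(0.25 / 40.5, rel=0.25)
        # non-degenerate group keeps its observed proportion 0.25
        assert draws[:, 1].mean() / 40 == pytest.approx(0.25, rel=0.05)


class TestBootstrap:
    def test_deterministic_under_seed(self, exact_ll2_data):
        spec = bk.BMRSpec(bmr=0.1, definition="excess")
        a = bootstrap_bmd(exact_ll2_data, "LL.2", spec, n_boot=60, seed=42)
        b = bootstrap_bmd(exact_ll2_data, "LL.2", spec, n_boot=60, seed=42)
        assert a.bmdl == b.bmdl
        assert np.array_equal(a.samples, b.samples)

    def test_sigma_zero_parametric_replicates_identical(self):
        data, truth = bk.generate(bk.validation_scenario(sd=0.1, seed=3))
        # degenerate: responses exactly on the curve, zero residual SD
        exact = bk.DoseResponseData(dose=data.dose,
                                    response_kind="continuous",
                                    response=np.asarray(
                                        truth.curve(data.dose), float))
        spec = bk.BMRSpec(bmr=0.05, definition="relative")
        res = bootstrap_bmd(exact, "LL.4", spec, kind="parametric",
                            n_boot=50, seed=5)
        fit = bk.fit_model(exact, "LL.4")
        bmd = solve_bmd(fit, spec).bmd
        assert res.bmdl == pytest.approx(bmd, rel=1e-4)
        assert np.ptp(res.samples) < 1e-6 * bmd

    def test_nonparametric_binomial_sampler_marginal(self):
        """Within-group resampling of Bernoulli outcomes is marginally
        Binom(N_i, Y_i/N_i); chi-square GOF on 10^4 draws, and an
        all-events group never yields an impossible proportion."""
        data = bk.DoseResponseData(dose=[1.0, 2.0], response_kind="binomial",
                                   events=[8, 20], trials=[20, 20])
        rng = np.random.default_rng(123)
        draws = np.array([resample(data, "nonparametric", rng).events
                          for _ in range(10_000)])
        assert np.all(draws[:, 1] == 20)  # all-events group stays certain
        obs = np.bincount(draws[:, 0].astype(int), minlength=21)
        expected = stats.binom.pmf(np.arange(21), 20, 0.4) * 10_000
        keep = expected > 5
        chi2 = np.sum((obs[keep] - expected[keep]) ** 2 / expected[keep])
        crit = stats.chi2.ppf(0.999, keep.sum() - 1)
        assert chi2 < crit

    def test_semiparametric_residuals_recentred(self):
        data, _ = bk.generate(bk.validation_scenario(sd=1.0, seed=9))
        fit = bk.fit_model(data, "LL.4")
        rng = np.random.default_rng(1)
        b = resample(data, "semiparametric", rng, fit=fit)
        # resampled responses stay within the residual span of the fit
        resid = data.response - fit.predict(data.dose)
        assert b.response.min() >= fit.predict(data.dose).min() + resid.min() - 1e-9
        assert len(b) == len(data)

    def test_semiparametric_rejected_for_binomial(self, exact_ll2_data):
        spec = bk.BMRSpec(bmr=0.1, definition="excess")
        with pytest.raises(InvalidModelError, match="continuous"):
            bootstrap_bmd(exact_ll2_data, "LL.2", spec,
                          kind="semiparametric", n_boot=50, seed=1)

    def test_small_n_boot_rejected(self, exact_ll2_data):
        with pytest.raises(InvalidModelError, match="n_boot"):
            bootstrap_bmd(exact_ll2_data, "LL.2",
                          bk.BMRSpec(bmr=0.1, definition="excess"),
                          n_boot=10, seed=1)

    def test_bootstrap_approaches_delta_with_group_size(self):
        """On well-specified LL2 data the bootstrap and delta BMDL
        converge as dose-group sizes grow."""
        spec = bk.BMRSpec(bmr=0.1, definition="excess",
                          background_type="specified_p0", p0_fixed=0.0)
        gaps = []
        for trials in (50, 500):
            sc = bk.ScenarioSpec(family="log_logistic",
                                 params={"b": -1.0, "c": 0.0, "d": 1.0,
                                         "e": 10.0},
                                 doses=(0.0, 1.25, 2.5, 5.0, 10.0, 20.0),
                                 noise="binomial", trials=trials, seed=31)
            data, _ = bk.generate(sc)
            fit = bk.fit_model(data, "LL.2")
            est = solve_bmd(fit, spec, compute_se=True)
            d = bmdl_delta(fit, est).bmdl
            b = bootstrap_bmd(data, "LL.2", spec, n_boot=300, seed=31).bmdl
            gaps.append(abs(b - d) / d)
        assert gaps[1] < gaps[0]


class TestSandwich:
    def test_reduces_to_model_based_when_B_equals_A(self, exact_ll2_fit):
        parts = sandwich_vcov(exact_ll2_fit, exact_ll2_fit.data)
        Ainv = np.linalg.inv(parts.A)
        forced = Ainv @ parts.A @ Ainv.T
        assert np.allclose(forced, Ainv, rtol=1e-8)

    def test_zero_residuals_zero_variance(self):
        data, truth = bk.generate(bk.validation_scenario(sd=0.1, seed=3))
        exact = bk.DoseResponseData(dose=data.dose,
                                    response_kind="continuous",
                                    response=np.asarray(
                                        truth.curve(data.dose), float))
        fit = bk.fit_model(exact, "LL.4")
        fit.sigma = 1.0  # scores are residual-proportional; avoid 0/0
        parts = sandwich_vcov(fit, exact)
        assert np.allclose(parts.B, 0.0, atol=1e-8)
        assert np.allclose(parts.vcov_sandwich, 0.0, atol=1e-8)

    def test_information_equality_for_correct_poisson(self):
        sc = bk.ScenarioSpec(family="log_logistic",
                             params={"b": 1.0, "c": 0.0, "d": 20.0, "e": 5.0},
                             doses=(0.0, 1.0, 3.0, 10.0, 30.0),
                             replicates=400, noise="poisson", seed=37)
        data, _ = bk.generate(sc)
        fit = bk.fit_model(data, "LL.3")
        sw = sandwich_vcov(fit, data)
        se_model = np.sqrt(np.diag(fit.vcov))
        se_sand = np.sqrt(np.diag(sw.vcov_sandwich))
        assert np.all(np.abs(se_sand / se_model - 1.0) < 0.15)

    def test_overdispersion_inflates_sandwich_se(self, fixture_suite):
        data, _ = fixture_suite["count_overdispersed"]
        fit = bk.fit_model(data, "LL.3")
        sw = sandwich_vcov(fit, data)
        se_model = np.sqrt(np.diag(fit.vcov))
        se_sand = np.sqrt(np.diag(sw.vcov_sandwich))
        assert np.all(se_sand > se_model)

    def test_symmetric_psd(self, exact_ll2_fit):
        V = sandwich_vcov(exact_ll2_fit, exact_ll2_fit.data).vcov_sandwich
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)
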