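import numpy as np
import pytest
from hypothesis import settings

import bmdkit as bk
from bmdkit.models import ModelFit, ModelSpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def exact_ll2_data():
    """Binomial observations lying exactly on the LL2 curve with b=-1,
    e=10 (f(d) = d/(d+10)): proportions 0.1/0.5/0.9 at doses 10/9, 10, 90."""
    return bk.DoseResponseData(
        dose=np.array([10.0 / 9.0, 10.0, 90.0]),
        response_kind="binomial",
        events=np.array([10.0, 50.0, 90.0]),
        trials=np.array([100.0, 100.0, 100.0]),
    )


@pytest.fixture(scope="session")
def exact_ll2_fit(exact_ll2_data):
    fit = bk.fit_model(exact_ll2_data, "LL.2")
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def validation_fit():
    """LL4 fit to one dataset from the continuous validation design
    (limits 2 and 10, sd 0.1, 10 replicates per dose)."""
    data, truth = bk.generate(bk.validation_scenario(sd=0.1, replicates=10,
                                                     seed=11))
    fit = bk.fit_model(data, "LL.4")
    assert fit.converged
    return data, truth, fit


@pytest.fixture(scope="session")
def fixture_suite():
    return bk.make_fixture_suite(seed=0)


def make_fit(family, params, fixed=None, distribution="binomial",
             vcov=None, sigma=None, data=None, direction=None):
    """Construct a ModelFit directly from known parameters (no data fit),
    for tests that exercise the BMD definitions on prescribed curves."""
    spec = ModelSpec(family=family, distribution=distribution,
                     fixed=fixed or {})
    free = spec.free_names
    beta = np.array([params[n] for n in free], dtype=float)
    p = len(free)
    fam = spec.family_obj
    f0 = fam.limit0(params)
    finf = fam.limit_inf(params)
    if direction is None:
        direction = "increasing" if finf >= f0 else "decreasing"
    return ModelFit(
        spec=spec, params=dict(params), beta=beta, free_names=free,
        vcov=np.zeros((p, p)) if vcov is None else np.asarray(vcov, float),
        loglik=0.0, aic=2.0 * p, bic=2.0 * p, residual_deviance=0.0,
        df_residual=1, n_obs=p + 1, converged=True, sigma=sigma,
        direction=direction, data=data,
    )
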