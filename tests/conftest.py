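"""Shared fixtures: reference model, study designs, and one expensive fit.

The session-scoped `default_fit` performs a single full-size simulate+fit
cycle that several diagnostic and exposure tests share.
"""

import warnings

import numpy as np
import pytest

import lactpk as lp

REF_THETA = dict(ka=1.87, cl=19.4, vc=184.0, kcb=0.245, rcb=1.77)


@pytest.fixture(scope="session")
def ref_model():
    return lp.PopulationModel.lamivudine_reference()


@pytest.fixture(scope="session")
def typical_params():
    return lp.StructuralParams(**REF_THETA)


@pytest.fixture(scope="session")
def default_design():
    return lp.StudyDesign()


@pytest.fixture(scope="session")
def small_design():
    return lp.StudyDesign(n_q12=4, n_q24=8, n_morning=6)


@pytest.fixture(scope="session")
def default_study(default_design, ref_model):
    return lp.simulate_study(default_design, ref_model, seed=1)


@pytest.fixture(scope="session")
def small_study(small_design, ref_model):
    return lp.simulate_study(small_design, ref_model, seed=11)


def perturbed_init(seed):
    """Reference values with fixed effects jittered by x[0.5, 2]."""
    rng = np.random.default_rng(1000 + seed)
    pert = np.exp(rng.uniform(np.log(0.5), np.log(2.0), 5))
    base = np.array([1.87, 19.4, 184.0, 0.245, 1.77]) * pert
    return lp.PopulationModel.from_cv(
        lp.StructuralParams(*base), 0.3, 0.5, 0.3, 0.0, 0.3, 0.3
    )


@pytest.fixture(scope="session")
def default_fit(default_study, ref_model):
    """Full-size fit of the default synthetic study (shared, expensive)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = lp.fit_model(default_study, perturbed_init(1))
    assert np.isfinite(fit.ofv)
    return fit


@pytest.fixture(scope="session")
def small_fit(small_study, ref_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return lp.fit_model(small_study, ref_model)
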