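import numpy as np
import pytest

from nodulegrowth import (
    NoduleSeries,
    ScanObservation,
    default_cohort_spec,
    generate_cohort,
    generate_fixture,
    vb_solve_forward,
)


def make_series(times, volumes, nodule_id="N1", malignancy="malignant", hu=None, **kw):
    hu = hu if hu is not None else [None] * len(times)
    obs = tuple(ScanObservation(t, v, h) for t, v, h in zip(times, volumes, hu))
    return NoduleSeries(nodule_id, malignancy, obs, **kw)


def forward_series(v0, alpha, beta, times=(0.0, 12.0, 24.0), **kw):
    vols = vb_solve_forward(v0, alpha, beta, times)
    return make_series(times, vols, **kw)


@pytest.fixture(scope="session")
def default_cohort():
    """Noiseless 180-nodule cohort with ground truth."""
    return generate_cohort(default_cohort_spec(), seed=11, return_truth=True)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_fixture("tiny")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
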