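"""Shared fixtures: small synthetic cohorts and derived feature tables.

Recording durations are kept just long enough to hold the epochs a test
uses — the generator is stationary, so extra duration adds information to
no test.  Expensive artifacts (feature tables, trained stacks) are
session-scoped.
"""

import numpy as np
import pytest

import eegsae
from eegsae.features import build_feature_dataset
from eegsae.preprocess import extract_cohort_epochs
from eegsae.stack import train_stack


@pytest.fixture(scope="session")
def small_spec():
    """4 CNT + 4 PNES subjects, enough signal for 10 epochs each."""
    return eegsae.CohortSpec(n_cnt=4, n_pnes=4, duration_s=60.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return eegsae.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    return extract_cohort_epochs(small_cohort, n_epochs=10)


@pytest.fixture(scope="session")
def small_features(small_epochs):
    return build_feature_dataset(small_epochs)


@pytest.fixture(scope="session")
def trained_stack(small_features):
    return train_stack(small_features)


@pytest.fixture(scope="session")
def tiny_recording():
    """One 30 s CNT recording for preprocessing tests."""
    spec = eegsae.CohortSpec(n_cnt=1, n_pnes=1, duration_s=30.0, seed=7)
    return eegsae.generate_recording("CNT", spec, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
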