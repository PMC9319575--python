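"""Shared fixtures: small synthetic records and tables.

Heavy objects (extracted feature dictionaries) are session-scoped so the
expensive entropy computations run once.
"""

import numpy as np
import pytest

from ehgselect import CohortSpec, TableSpec, generate_record
from ehgselect.features import extract_record
from ehgselect.synthetic import generate_feature_table


@pytest.fixture(scope="session")
def short_spec():
    """240 s clean cohort spec: 3 windows per channel, no artifacts."""
    return CohortSpec(n_preterm=2, n_term=2, duration_s=240.0,
                      artifact_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def short_record(short_spec):
    return generate_record("term", short_spec, seed=1234, record_id="T001")


@pytest.fixture(scope="session")
def short_record_features(short_record):
    return extract_record(short_record)


@pytest.fixture(scope="session")
def separable_table():
    """Strong-separation Gaussian table: LDA is near-perfect on it."""
    return generate_feature_table(
        TableSpec(n_minority=40, n_majority=160, n_informative=5,
                  n_noise=15, separation=6.0, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(987)
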