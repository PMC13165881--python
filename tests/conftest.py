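"""Shared fixtures: a planted synthetic cohort and trained models.

Session-scoped so the (deterministic) trainings run once for the whole
suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eeglatent import (
    TaeConfig,
    TransformerAutoencoder,
    VaeConfig,
    VariationalAutoencoder,
)
from eeglatent.session_io import zscore_matrix
from eeglatent.synth import CohortConfig, sample_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def cohort_std(default_cfg):
    """Standardized 96-session planted cohort (6 patients x (6,5,5))."""
    return zscore_matrix(sample_cohort(default_cfg))


@pytest.fixture(scope="session")
def tae_results(cohort_std):
    return TransformerAutoencoder(cohort_std, TaeConfig(seed=1)).fit()


@pytest.fixture(scope="session")
def vae_results(cohort_std):
    return VariationalAutoencoder(cohort_std, VaeConfig(seed=1)).fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
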