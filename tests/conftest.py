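"""Shared fixtures.

Heavy artefacts (the default 3/22/7 cohort, its feature matrix and the
SMOTE+ENN-balanced version) are built once per session; the seed is fixed so
every test sees the same stated world.
"""

import numpy as np
import pytest

from sarcoemg import (BalancingParams, CohortSpec, PipelineConfig,
                      extract_cohort_features, generate_cohort, smote_enn)

SESSION_SEED = 11


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def cohort():
    """The default imbalanced cohort: 3/22/7 subjects across levels 1/2/3."""
    return generate_cohort(CohortSpec(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def feature_matrix(cohort, config):
    """48-column per-subject feature matrix of the default cohort."""
    return extract_cohort_features(cohort, config)


@pytest.fixture(scope="session")
def balanced_matrix(feature_matrix):
    """Paper-style globally balanced matrix (~50 instances per level)."""
    return smote_enn(feature_matrix,
                     BalancingParams(target=50, seed=SESSION_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SESSION_SEED)
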