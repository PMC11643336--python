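import numpy as np
import pytest

import moveprof as mp


@pytest.fixture(scope="session")
def small_cohort():
    """3-subject default cohort shared across tests (generation is costly)."""
    cfg = mp.CohortConfig(n_subjects=3, seed=123)
    sessions, truth = mp.generate_cohort(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, sessions, _ = small_cohort
    table, review = mp.cohort_features(sessions)
    return table


@pytest.fixture(scope="session")
def one_session():
    """Single-subject, single-movement session with known structure."""
    archs = mp.build_default_archetypes()
    cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",), seed=7)
    profile = mp.default_profiles()["high"]
    return mp.generate_subject(archs, profile, cfg, seed=7, subject_id="S00")


def rng(seed=0):
    return np.random.default_rng(seed)
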