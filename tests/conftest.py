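import numpy as np
import pytest

from fearcortex.cohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across read-only tests."""
    cfg = CohortConfig(
        n_conditioned=4,
        n_pseudo=2,
        neurons_per_mouse=(20, 30),
        repeats_per_frequency=15,
        n_sessions=6,
        n_pre_sessions=3,
        seed=7,
        include_rois=True,
        n_rois_per_session=30,
    )
    return generate_cohort(cfg)
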