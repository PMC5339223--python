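import numpy as np
import pytest

from angermarkers.cohort import CohortSimulator


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort at generator defaults (shared across tests)."""
    return CohortSimulator(n_subjects=6).simulate(seed=3)


@pytest.fixture(scope="session")
def default_simulator():
    return CohortSimulator(n_subjects=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
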