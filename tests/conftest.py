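import numpy as np
import pytest

from reciprosim import RunConfig
from reciprosim.pipeline import TrialLog, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_log() -> TrialLog:
    """A 4-per-group cohort shared across tests (seed fixed)."""
    return simulate_cohort(RunConfig(n_per_group=4, seed=7))


@pytest.fixture(scope="session")
def default_cohort_log() -> TrialLog:
    """The calibrated 25-per-group cohort used by the acceptance tests."""
    return simulate_cohort(RunConfig(n_per_group=25, seed=2024))
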