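import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from itug.synthetic import simulate_cohort, simulate_trial

settings.register_profile(
    "suite",
    settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Five subjects (3 community, 2 outpatient) with clinical table."""
    return simulate_cohort(3, 2, seed=11)


@pytest.fixture(scope="session")
def profiles(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def trial(profiles):
    """One noisy repetition of the first subject with its ground truth."""
    return simulate_trial(profiles[0], repetition=0, seed=5)


@pytest.fixture(scope="session")
def noiseless_trial(profiles):
    return simulate_trial(
        profiles[0], repetition=0, seed=5, noise_acc_sd=0.0, noise_gyro_sd=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
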