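import pytest
from hypothesis import HealthCheck, settings

from rpqscat import calibrate_defaults, simulate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size simulated cohort under the shipped defaults."""
    return simulate_cohort(calibrate_defaults(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-subject cohort for tests that scale quadratically or hit disk."""
    return simulate_cohort(calibrate_defaults(seed=3, n_subjects=50))
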