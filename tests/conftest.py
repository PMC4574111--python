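"""Shared fixtures and hypothesis settings for the test suite."""

import pytest
from hypothesis import HealthCheck, settings

from rhythmbat import battery, simulate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def plan():
    """One fixed battery plan shared by all tests that need a schedule."""
    return battery.make_battery(seed=0)


@pytest.fixture(scope="session")
def scores65():
    """Scored default cohort (n=65, seed 0, independent latents)."""
    return simulate.simulate_scores(seed=0)
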