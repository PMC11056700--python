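import pytest
from hypothesis import HealthCheck, settings

import msmtrial as m
from msmtrial.synthetic_data import (
    default_hovon_like_config,
    recovery_config,
    simulate_trial,
    worked_fixture,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_records():
    return worked_fixture()


@pytest.fixture(scope="session")
def model1():
    return m.model1_offprotocol()


@pytest.fixture(scope="session")
def model2():
    return m.model2_mrd()


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated trial-sized cohort under the default configuration."""
    return simulate_trial(default_hovon_like_config(), seed=42)


@pytest.fixture(scope="session")
def recovery_cohort():
    """A large cohort with known arm and origin-state hazard ratios."""
    cfg = recovery_config(n_per_arm=1000)
    return cfg, simulate_trial(cfg, seed=7)
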