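import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copdwatch as cw

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort for fast structural checks."""
    return cw.SimConfig(n_patients=20, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cw.simulate_cohort_tables(small_config)


@pytest.fixture(scope="session")
def medium_table():
    """A 300-patient period table for fitting tests (no daily logs)."""
    cfg = cw.SimConfig(n_patients=300, seed=7)
    profiles, pre, post, _ = cw.simulate_cohort_tables(cfg, daily=False)
    return cw.build_period_table(profiles, pre, post)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
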