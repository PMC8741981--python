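import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import weanpower as wp

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort with the study's default two-group structure."""
    return wp.generate_cohort(wp.CohortSpec(seed=42))


@pytest.fixture(scope="session")
def default_panels(default_cohort):
    return [wp.compute_panel(r) for r in default_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
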