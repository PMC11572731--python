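import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prl_mediation.generate import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_cohort():
    """Default study-calibrated linear-mode cohort (117 BA / 123 WA)."""
    return generate_cohort(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def count_cohort():
    """Default study-calibrated count-mode cohort."""
    return generate_cohort(GeneratorConfig(mode="count", seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
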