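import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pedfl.synth import GeneratorConfig, sample_cohort

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_1672():
    """One full-size synthetic cohort (outcomes from the BMI equation)."""
    return sample_cohort(GeneratorConfig(n=1672, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast model-fitting tests."""
    return sample_cohort(GeneratorConfig(n=400, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
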