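import numpy as np
import pytest
from hypothesis import settings

from kidscore.model import KidThresholds
from kidscore.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


@pytest.fixture(scope="session")
def thresholds() -> KidThresholds:
    return KidThresholds()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130215)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort at the study's group sizes."""
    return generate_cohort(GeneratorConfig(seed=11))
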