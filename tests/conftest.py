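import numpy as np
import pytest
from hypothesis import settings

from cohesion.synthetic import SimulationConfig

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(20130822)


@pytest.fixture
def wt_config():
    """Wild-type slow-growth conditions (minimal alanine, 30°C)."""
    return SimulationConfig(seed=7, generation_time=119.0, cohesion_minutes=31.0)
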