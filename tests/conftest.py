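import numpy as np
import pytest

from mitescan.synthetic_data import SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(11)
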