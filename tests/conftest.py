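import numpy as np
import pytest

from feedscape import SimulationConfig


@pytest.fixture
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def tiny_cfg() -> SimulationConfig:
    """Desk-scale config for fast dynamics tests: 4 agents, 2x2 box, 4 s."""
    return SimulationConfig(N=4, L=2.0, duration=4.0, analysis_window=2.0, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
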