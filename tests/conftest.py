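import numpy as np
import pytest

from angioca.core import ModelParams, SimulationGrid


@pytest.fixture
def params():
    """Small-grid parameter set for fast unit tests."""
    return ModelParams(grid_n=60)


@pytest.fixture
def grid(params):
    return SimulationGrid(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
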