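import numpy as np
import pytest

from cyanoprospect.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)
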