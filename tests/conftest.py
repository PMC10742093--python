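import numpy as np
import pytest

from predprey.config import SimConfig


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture
def small_cfg() -> SimConfig:
    """A fast world for engine-level tests: same physics, short horizon."""
    return SimConfig(n_steps=100, seed=7)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(12345)
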