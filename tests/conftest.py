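import numpy as np
import pytest

from abmcontrol import GridConfig
from abmcontrol.reaction_abm import scaled_config


@pytest.fixture
def small_grid() -> GridConfig:
    """A 64 x 64 world at roughly the study's agent densities: fast enough
    for per-test rollouts while keeping the same per-cell dynamics."""
    return GridConfig(L=64, b0=160, c0=80)


@pytest.fixture
def small_pathway():
    """Desk-scale pathway configuration (counts / 100, 60 x 60, 2000
    periods)."""
    return scaled_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
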