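import numpy as np
import pytest

from infraccess.grid import GridLayer
from infraccess.synthetic import WorldConfig, generate_world


def make_layer(values, mask=None, cell=0.1, origin=(90.0, -180.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    return GridLayer(values=values, mask=np.asarray(mask, bool), cell_size_deg=cell, origin=origin)


@pytest.fixture(scope="session")
def small_config():
    """A compact world: 24 countries on a 48x96 grid, everything else default."""
    return WorldConfig(seed=11, grid_shape=(48, 96), n_countries=24, counties_per_country=4)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
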