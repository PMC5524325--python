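import numpy as np
import pytest

from pamonitor import (
    GridGeometry,
    LULCMap,
    PALETTE,
    default_landscape_config,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_config():
    return default_landscape_config(rows=96, cols=96, cell_size=50.0, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    """(scene_t1, scene_t2, truth_t1, truth_t2) on a 4.8-km square."""
    return generate_landscape(small_config, seed=11)


@pytest.fixture(scope="session")
def default_landscape():
    cfg = default_landscape_config(seed=3)
    return cfg, generate_landscape(cfg, seed=3)


def make_lulc(data, cell_size=50.0, palette=PALETTE):
    data = np.asarray(data, dtype=np.int16)
    geom = GridGeometry(0.0, data.shape[0] * cell_size, cell_size, *data.shape)
    return LULCMap(data, palette, geom)


@pytest.fixture()
def uniform_lulc():
    """Homogeneous closed-shrubland map, 60 x 60 cells of 50 m."""
    return make_lulc(np.full((60, 60), 2))
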