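import numpy as np
import pytest

from guildscape.landscape import CategoricalRaster


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def uniform_raster():
    return CategoricalRaster(np.ones((10, 10), dtype=int), 10.0)


@pytest.fixture
def two_class_raster():
    v = np.ones((20, 20), dtype=int)
    v[:, 10:] = 2
    return CategoricalRaster(v, 10.0)


def random_raster(rng, shape=(12, 12), n_classes=3, p_nodata=0.0):
    v = rng.integers(1, n_classes + 1, size=shape)
    if p_nodata > 0:
        v[rng.random(shape) < p_nodata] = -1
    return CategoricalRaster(v, 10.0)
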