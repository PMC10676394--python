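import numpy as np
import pytest

from pharmaniche.io_geo import EnvStack, GridSpec, RasterLayer
from pharmaniche.synthetic_data import default_scene


@pytest.fixture(scope="session")
def scene():
    """The default synthetic study scene (100×100, 12+1 layers, 200 presences)."""
    return default_scene(seed=11)


@pytest.fixture(scope="session")
def small_scene():
    """A light scene for fast structural tests."""
    return default_scene(seed=7, nrows=40, ncols=40, n_points=80)


@pytest.fixture
def tiny_spec():
    return GridSpec(ncols=4, nrows=3, xllcorner=10.0, yllcorner=40.0, cellsize=0.5)


@pytest.fixture
def tiny_layer(tiny_spec):
    vals = np.arange(12, dtype=float).reshape(3, 4)
    return RasterLayer("demo", tiny_spec, np.ma.asarray(vals))


@pytest.fixture
def tiny_stack(tiny_spec):
    rng = np.random.default_rng(0)
    layers = [
        RasterLayer("a", tiny_spec, np.ma.asarray(rng.normal(size=(3, 4)))),
        RasterLayer("b", tiny_spec, np.ma.asarray(rng.normal(size=(3, 4)))),
    ]
    return EnvStack(layers)
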