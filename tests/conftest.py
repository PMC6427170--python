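import numpy as np
import pytest

from greenexposure import RasterGrid, SceneConfig, generate_stack, sample_addresses


@pytest.fixture
def rng():
    return np.random.default_rng(20060625)


@pytest.fixture
def random_grid(rng):
    """A 20x20 100 m grid of uniform values on [0, 0.9] with a few holes."""
    values = rng.uniform(0.0, 0.9, size=(20, 20))
    valid = rng.random((20, 20)) > 0.1
    return RasterGrid(values=values, origin_x=1000.0, origin_y=5000.0, cell_size=100.0, valid=valid)


@pytest.fixture(scope="session")
def small_scene_config():
    """A fast scene: 5 km x 5 km, four years, defaults otherwise."""
    return SceneConfig(
        extent=(0.0, 0.0, 5000.0, 5000.0),
        years=(2006, 2007, 2008, 2009),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_stack(small_scene_config):
    return generate_stack(small_scene_config)


@pytest.fixture(scope="session")
def small_addresses(small_scene_config):
    return sample_addresses(40, small_scene_config)
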