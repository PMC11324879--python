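import numpy as np
import pytest

from cloudshift.raster import Grid
from cloudshift.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def quiet_scene():
    """Small noise-free scene: every recovery check should be exact."""
    cfg = SceneConfig(grid_shape=(40, 40), noise_sd_K=0.0, nodata_frac=0.0,
                      n_loss_events=10, seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    cfg = SceneConfig(grid_shape=(60, 60), noise_sd_K=0.3, n_loss_events=12, seed=7)
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def grid(values, pixel_size=1000.0, origin=(0.0, 0.0)):
    return Grid(np.asarray(values, dtype=float), origin=origin, pixel_size=pixel_size)


@pytest.fixture()
def make_grid():
    return grid
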