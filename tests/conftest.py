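import numpy as np
import pytest

from peatwatch.grid import RasterGrid
from peatwatch.preprocess import N_BANDS, Composite, SceneStack, Sensor
from peatwatch.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return RasterGrid.square(10, 12)


def make_scene(grid, bands=None, thermal=None, qa=None, year=2000, doy=170,
               sensor=Sensor.SYNTHETIC, rng=None):
    rows, cols = grid.shape
    if bands is None:
        rng = rng or np.random.default_rng(0)
        bands = rng.uniform(0.01, 0.6, size=(N_BANDS, rows, cols))
    if thermal is None:
        thermal = np.full((rows, cols), 295.0)
    if qa is None:
        qa = np.zeros((rows, cols), dtype=np.uint16)
    return SceneStack(year=year, acquisition_doy=doy, sensor_id=sensor,
                      bands=np.asarray(bands, dtype=np.float64),
                      thermal=np.asarray(thermal, dtype=np.float64),
                      qa=np.asarray(qa), grid=grid)


def make_composite(grid, bands=None, thermal=None, year=2000, rng=None):
    rows, cols = grid.shape
    if bands is None:
        rng = rng or np.random.default_rng(0)
        bands = rng.uniform(0.01, 0.6, size=(N_BANDS, rows, cols))
    if thermal is None:
        thermal = np.full((rows, cols), 295.0)
    return Composite(year=year, bands=np.asarray(bands, dtype=np.float64),
                     thermal=np.asarray(thermal, dtype=np.float64), grid=grid,
                     valid_count=np.ones((rows, cols), dtype=np.int32))


@pytest.fixture
def tiny_config():
    return SimulationConfig(
        grid_rows=30, grid_cols=30,
        years=tuple(range(1984, 1994)),
        spectral_noise_sd=0.01,
        scenes_per_year=1,
        seed=7,
    )
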