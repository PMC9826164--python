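import numpy as np
import pytest

from ifmaudit.geodata_io import AnnualRasterStack, grid_transform
from ifmaudit.synthetic_landscape import LandscapeConfig, generate_scene


def make_stack(values, years=None, cell=30.0, nodata=None, units="ton C/ha"):
    """Stack from an array shaped (years, rows, cols) on a simple north-up grid."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    if years is None:
        years = np.arange(2000, 2000 + values.shape[0])
    rows = values.shape[1]
    return AnnualRasterStack(values, np.asarray(years), grid_transform(0.0, rows * cell, cell),
                             crs="local-m", nodata=nodata, units=units)


@pytest.fixture(scope="session")
def default_scene():
    """One full-size scene at the generator defaults, shared across tests."""
    return generate_scene(LandscapeConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_scene():
    """A smaller, quicker scene for plumbing-level tests."""
    cfg = LandscapeConfig(grid_shape=(72, 72), n_projects=2,
                          project_area_range=(20.0, 35.0), rng_seed=7)
    return generate_scene(cfg)
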