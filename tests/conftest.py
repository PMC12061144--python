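import numpy as np
import pandas as pd
import pytest

from nichetransfer.geodata import OccurrenceSet, PredictorStack, RasterGrid


def make_grid(values, origin_lon=0.0, origin_lat=10.0, cell_size=0.5, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return RasterGrid(values, mask, origin_lon, origin_lat, cell_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_stack(rng):
    """20x20 two-predictor stack with a few nodata cells."""
    shape = (20, 20)
    mask = np.zeros(shape, dtype=bool)
    mask[3, 4] = mask[17, 2] = True
    lat = 10.0 - (np.arange(20) + 0.5) * 0.5
    grad = np.repeat(lat[:, None], 20, axis=1)
    noise = rng.standard_normal(shape)
    grids = {
        "bio1": make_grid(np.where(mask, np.nan, grad), mask=mask),
        "elevation": make_grid(np.where(mask, np.nan, noise), mask=mask),
    }
    return PredictorStack(grids, {"bio1": "climate", "elevation": "topography"})


@pytest.fixture
def occurrences_df():
    return pd.DataFrame(
        {
            "population": ["a", "a", "b"],
            "lon": [1.25, 3.75, 2.25],
            "lat": [9.75, 8.25, 7.75],
            "source": ["gbif", "gbif", "lit"],
        }
    )


@pytest.fixture
def occurrences(occurrences_df):
    return OccurrenceSet(occurrences_df)


@pytest.fixture(scope="session")
def scenario():
    """Session-wide default synthetic scenario (fixed seed)."""
    from nichetransfer.synthetic import default_scenario

    return default_scenario(seed=1)


try:  # keep property-based tests deterministic across runs
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True, deadline=None)
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover
    pass
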