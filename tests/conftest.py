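import numpy as np
import pandas as pd
import pytest

from nichemap.grids import GridSpec, RasterLayer, RasterStack, RegionMask
from nichemap.occurrences import OccurrenceSet
from nichemap.synthetic_data import SyntheticScenario


@pytest.fixture
def small_spec():
    """A 6x8 one-degree grid for hand-checkable geometry."""
    return GridSpec(n_rows=6, n_cols=8, x_min=0.0, y_min=0.0, cell_size=1.0)


@pytest.fixture
def small_scenario():
    """A reduced synthetic scenario for fast unit tests."""
    return SyntheticScenario(n_rows=40, n_cols=50, seed=7)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard study conditions (120 x 160 grid)."""
    return SyntheticScenario()


def make_layer(spec, values, name="layer", mask=None):
    return RasterLayer(spec, name, np.asarray(values, float), mask)


def make_points(lon, lat):
    return OccurrenceSet(
        pd.DataFrame({"lon": lon, "lat": lat, "source": "test"})
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
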