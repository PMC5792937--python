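import numpy as np
import pandas as pd
import pytest

from nichephylo.geodata import (CATEGORICAL, CONTINUOUS, EnvStack,
                                OccurrenceSet, RasterGrid)


@pytest.fixture
def small_grid():
    """5x5 fully valid grid with a simple gradient."""
    vals = np.linspace(0, 1, 25).reshape(5, 5)
    return RasterGrid(vals, np.zeros((5, 5), bool), 0.0, 0.0, 1.0, name="grad")


@pytest.fixture
def small_stack(small_grid):
    rng = np.random.default_rng(7)
    other = RasterGrid(rng.uniform(size=(5, 5)), np.zeros((5, 5), bool),
                       0.0, 0.0, 1.0, name="noise")
    cat = RasterGrid(np.tile([0., 1., 2., 1., 0.], (5, 1)),
                     np.zeros((5, 5), bool), 0.0, 0.0, 1.0, name="soil")
    return EnvStack([small_grid, other, cat],
                    [CONTINUOUS, CONTINUOUS, CATEGORICAL])


@pytest.fixture
def two_cell_problem():
    """1x2 domain with env values 0 and 1; presence mean 0.75.

    The unpenalised linear-feature maxent solution is exactly
    lambda = ln 3 with raw map (0.25, 0.75).
    """
    from nichephylo.maxent_sdm import build_features
    grid = RasterGrid(np.array([[0.0, 1.0]]), np.zeros((1, 2), bool),
                      0.0, 0.0, 1.0, name="env")
    stack = EnvStack([grid], [CONTINUOUS])
    features = build_features(stack, 4, mode=["linear"])
    presence_rows = np.array([1, 1, 1, 0])  # mean feature value = 0.75
    return features, presence_rows


def make_occurrences(points):
    """points: list of (species, lon, lat) tuples."""
    df = pd.DataFrame(points, columns=["species", "longitude", "latitude"])
    return OccurrenceSet(df)
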