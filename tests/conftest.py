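import numpy as np
import pytest

from replitime.grid import LocusGrid, TrackValues, build_grid


@pytest.fixture
def small_grid() -> LocusGrid:
    """Two tiny chromosomes, one with a partial terminal bin."""
    return build_grid({"chrA": 10_000, "chrB": 5_500}, bin_width=1000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_track(grid: LocusGrid, values, mask=None) -> TrackValues:
    v = np.asarray(values, dtype=float)
    return TrackValues(grid, v, mask)
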