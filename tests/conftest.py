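import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from replitime.genome import BinGrid, GenomeLayout
from replitime.tracks import BinnedTrack, RTProfile

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def layout_1mb() -> GenomeLayout:
    return GenomeLayout.from_pairs([("chr1", 1_000_000)])


@pytest.fixture
def grid_50kb(layout_1mb) -> BinGrid:
    return BinGrid(layout_1mb, 50_000)


def make_profile(grid: BinGrid, values, valid=None) -> RTProfile:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return RTProfile(grid, values, np.asarray(valid, dtype=bool))


def make_track(grid: BinGrid, values, valid=None) -> BinnedTrack:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return BinnedTrack(grid, values, np.asarray(valid, dtype=bool))
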