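"""Shared fixtures: one modest synthetic ensemble reused across test modules."""

import numpy as np
import pytest

from cofirepy import coactivity as co
from cofirepy import synthetic as syn


@pytest.fixture(scope="session")
def truth():
    return syn.make_ground_truth(n_cells=120, seed=11)


@pytest.fixture(scope="session")
def day1_recordings(truth):
    """Four interleaved 5-min trials (2 cylinder, 2 square) on day 1."""
    return syn.generate_ensemble_pair(truth, syn.Protocol(days=(1,)), seed=12)


@pytest.fixture(scope="session")
def day1_binned(day1_recordings):
    return [co.bin_to_1s(r.raster) for r in day1_recordings]


@pytest.fixture(scope="session")
def day1_tau(day1_recordings, day1_binned):
    """Coactivity matrix of the first cylinder trial."""
    return co.kendall_matrix(day1_binned[0], coords=day1_recordings[0].soma_um)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
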