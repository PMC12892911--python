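import numpy as np
import pytest

from zebraphen import simulate as sim
from zebraphen.datatypes import StimulusProtocol


@pytest.fixture(scope="session")
def simple_protocol():
    return StimulusProtocol.simple()


@pytest.fixture(scope="session")
def extended_protocol():
    return StimulusProtocol.extended()


@pytest.fixture(scope="session")
def default_plate():
    """One 94-well plate from the default in-cross mixture."""
    return sim.simulate_plate(n_wells=94, seed=11)


def brute_percentile(values, q):
    """Independent rank-based percentile: linear interpolation of order stats."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])
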