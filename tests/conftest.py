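import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from streamfdr.io import stampede_fixture


@pytest.fixture(scope="session")
def stampede():
    return stampede_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_stream(rng, n, spiky=True):
    """A p-value stream with a mix of small and large values so that online
    policies actually reject sometimes."""
    p = rng.random(n)
    if spiky:
        hot = rng.random(n) < 0.3
        p[hot] = p[hot] * 1e-3
    return p


@pytest.fixture
def stream_factory(rng):
    def make(n, spiky=True):
        return random_stream(rng, n, spiky=spiky)

    return make
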