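import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def uniform_pair(rng):
    """A fixed pair of independent uniform phase samples, n = 256."""
    return (
        rng.uniform(-np.pi, np.pi, 256),
        rng.uniform(-np.pi, np.pi, 256),
    )
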