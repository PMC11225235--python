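import numpy as np
import pytest

from cfdeconv import simulate_atlas


@pytest.fixture
def tiny_atlas():
    """3 entities (1 tumor + 2 backgrounds), 100 regions, 10 markers each."""
    return simulate_atlas(3, 100, 10, margin=0.5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
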