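import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_signal(rng):
    """Static 2-block correlated signal: 12 nodes, 120 volumes, TR 1 s."""
    n_vol, n_nodes = 120, 12
    latents = rng.standard_normal((n_vol, 2))
    block = np.repeat([0, 1], n_nodes // 2)
    data = 0.9 * latents[:, block] + 0.45 * rng.standard_normal((n_vol, n_nodes))
    return data, block
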