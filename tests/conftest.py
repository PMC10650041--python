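import numpy as np
import pytest

from cfanet.network import CFANet, NetworkConfig
from cfanet.synthetic import SceneConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_net():
    """One fully assembled default network shared across read-only tests."""
    return CFANet(NetworkConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 64x64 synthetic samples for fast training smoke tests."""
    cfg = SceneConfig(image_size=64, seed=99, max_foreground_fraction=0.02)
    gen = np.random.default_rng(99)
    return [generate_sample(cfg, gen) for _ in range(8)]
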