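import numpy as np
import pytest

from sgbnet import synthetic
from sgbnet.model import ModelConfig

# a slim configuration that preserves every architectural contract
TINY_CONFIG = ModelConfig(
    channels=(8, 12, 16, 20),
    blocks=(1, 1, 1, 1),
    sa_width=8,
    ae_widths=(12, 10, 8),
    br_width=8,
    fuse_width=8,
)


@pytest.fixture
def tiny_config():
    return TINY_CONFIG


@pytest.fixture(scope="session")
def synth_sample():
    """One deterministic 128x128 synthetic fundus sample."""
    return synthetic.generate(
        synthetic.SynthParams(seed=42, size=(128, 128), n_trees=3,
                              branch_depth=4, n_lesions=2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
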