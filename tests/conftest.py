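import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    from kandescod.backbone import DenoiserConfig
    return DenoiserConfig(hidden_features=4, n_levels=2, blocks_per_level=1,
                          segment_length=64, embedding_dim=8, conditioning_kind="kan")
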