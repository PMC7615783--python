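import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_model_config():
    """Small architecture used across model-level tests."""
    from csagp import ModelConfig

    return ModelConfig(K=2, M=1, N_enc=1, D=16, h=2, ffn_mult=2, C=2,
                       img_size=(32, 32), seed=0)
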