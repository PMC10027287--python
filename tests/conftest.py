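import numpy as np
import pytest

from ssplearn.nn import ModelConfig
from ssplearn.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A model small enough for finite-difference checks and fast unit tests."""
    return ModelConfig(d_model=8, n_encoder_layers=1, n_heads=2, gru_hidden=4,
                      gru_layers=1, proj_dim=4, dropout=0.0, max_len=32, seed=0)


@pytest.fixture
def small_dataset():
    """20 short labeled+structured peptides, motif-implanted, fully seeded."""
    return generate(SyntheticSpec(n_pos=10, n_neg=10, length_range=(12, 20), seed=7))
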