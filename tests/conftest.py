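import numpy as np
import pytest

from ggn import network as net
from ggn import synthetic_data as sd


@pytest.fixture(scope="session")
def fn_recording():
    """A short FN-like recording with its planted connectivity."""
    return sd.generate_recording("FN", duration_s=30, fs=250, seed=11)


@pytest.fixture(scope="session")
def resting_recording():
    return sd.generate_recording("resting", duration_s=30, fs=250, seed=12)


@pytest.fixture
def tiny_config():
    """A minimal architecture for fast training-path tests."""
    return net.GGNConfig(n_channels=4, n_classes=2, c_in=2, t_steps=3,
                         c_enc=4, enc_layers=1, embed_dim=4, mpnn_rounds=1,
                         k_mix=2, m_graphs=2, k_family=2, c_out=4,
                         decoder_layers=1, cnn_filters=2, fc_hidden=8)


@pytest.fixture
def tiny_batch(tiny_config):
    rng = np.random.default_rng(3)
    cfg = tiny_config
    x = rng.normal(size=(5, cfg.n_channels, cfg.c_in, cfg.t_steps))
    a0 = np.abs(rng.normal(size=(cfg.n_channels, cfg.n_channels)))
    a0 = 0.5 * (a0 + a0.T)
    np.fill_diagonal(a0, 0.0)
    labels = np.array([0, 1, 0, 1, 1])
    return x, a0, labels
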