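import numpy as np
import pytest

from driverfusion import ModelConfig, SyntheticConfig, TrainConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_synth():
    """A small planted-signal dataset shared by training-level tests."""
    cfg = SyntheticConfig(
        n_genes=80,
        n_drivers=12,
        n_negatives=32,
        n_features=12,
        n_sets=15,
        edge_density=0.08,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture
def tiny_model_config():
    return ModelConfig(d=16, n_layers=1, n_heads=2, dropout=0.0)


@pytest.fixture
def fast_train_config():
    return TrainConfig(learning_rate=0.01, epochs=30, seed=3)
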