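import numpy as np
import pytest

from gaitkinetics import (ModelConfig, SimConfig, TrainConfig,
                          generate_dataset, window_dataset)


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny cohort used by most structural tests."""
    return SimConfig(n_subjects=3, trials_per_subject=1, trial_length=150,
                     seed=11)


@pytest.fixture(scope="session")
def small_recordings(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_windows(small_recordings):
    return window_dataset(small_recordings)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Small-width model config so forward passes stay fast."""
    return ModelConfig(hidden_dim=16, gcn_node_out=4, projection_dim=32,
                       head_hidden=16, window=50, seed=3)


@pytest.fixture(scope="session")
def short_train_cfg():
    return TrainConfig(epochs=2, patience=2, batch_size=32, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
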