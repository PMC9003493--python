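import numpy as np
import pytest

from hydrosip import (
    NetArchitecture,
    PipelineConfig,
    SimConfig,
    TrainConfig,
    features_matrix,
    simulate_episode_dataset,
    simulate_sip_height_sequence,
    train,
    train_first_sip_detector,
)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def episode_dataset():
    """200 balanced labeled episodes through the real preprocessing path."""
    episodes, labels = simulate_episode_dataset(100, 100, seed=0)
    return episodes, labels


@pytest.fixture(scope="session")
def sip_model(episode_dataset, default_config):
    """A 1-hidden-layer, 3-neuron sip classifier trained on synthetic episodes."""
    episodes, labels = episode_dataset
    X = features_matrix(episodes, default_config)
    model, history = train(
        X, labels, NetArchitecture(n_inputs=5, hidden_sizes=(3,)),
        TrainConfig(seed=0),
    )
    return model, history


@pytest.fixture(scope="session")
def firstsip_model():
    """A 3-input first-sip detector trained on noise-free height cycles."""
    heights, flags = simulate_sip_height_sequence(12, 6, base=2.0, increment=0.15, seed=0)
    model, history = train_first_sip_detector(heights, flags, seed=0)
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
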