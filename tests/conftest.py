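import numpy as np
import pytest

from measort.simulate import (
    SimulationConfig,
    make_templates,
    simulate_recording,
)
from measort.sort import NetworkSpec, TrainConfig


@pytest.fixture(scope="session")
def two_blob_features():
    """Two well-separated Gaussian blobs in 63-d, labels attached."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.5, size=(300, 63))
    b = rng.normal(0.0, 0.5, size=(300, 63)) + 6.0
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 300)
    perm = rng.permutation(len(X))
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def quick_config():
    """Small training budget for contract tests on tiny fixtures."""
    return TrainConfig(pretrain_epochs=15, finetune_iterations=400,
                       batch_size=64, update_interval=20, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    return NetworkSpec(layer_sizes=(63, 64, 16, 4))


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free recording of 5 isolated units with its templates."""
    templates = make_templates(5, 64, (-100.0, -120.0), rng_seed=3)
    config = SimulationConfig(
        n_neurons=5, firing_rates=1.0, duration=100.0, noise_sd=0.0, seed=4
    )
    rec, truth = simulate_recording(templates, config)
    return rec, truth, templates
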