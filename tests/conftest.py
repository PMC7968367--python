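import numpy as np
import pytest

from cgmforecast.forecaster import ModelConfig
from cgmforecast.synthetic import SimulationConfig, generate_patient, no_fault_config


@pytest.fixture(scope="session")
def small_patient():
    """Two days of faulted synthetic data (shared, read-only)."""
    return generate_patient(SimulationConfig(seed=42, days=2))


@pytest.fixture(scope="session")
def clean_patient():
    """Three days without sensor faults (shared, read-only)."""
    return generate_patient(no_fault_config(seed=7, days=3))


@pytest.fixture
def tiny_model_config():
    """A forecaster configuration small enough for second-scale training."""
    return ModelConfig(
        hidden_units=6,
        dense_sizes=(8, 4),
        dense_activations=("relu", "relu"),
        batch_size=64,
        max_epochs=5,
        patience=5,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
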