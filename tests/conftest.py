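import numpy as np
import pytest

from delayformer.lorenz import LorenzConfig, simulate_coupled_lorenz
from delayformer.model import ModelConfig


@pytest.fixture(scope="session")
def lorenz30():
    """The default 30-variable, 5000-sample, time-invariant benchmark series."""
    return simulate_coupled_lorenz(LorenzConfig())


@pytest.fixture(scope="session")
def lorenz_small():
    """A short 6-variable series for fast training tests."""
    return simulate_coupled_lorenz(LorenzConfig(n_subsystems=2, n_samples=600, seed=1))


def tiny_model_config(**overrides) -> ModelConfig:
    """A small but non-trivial geometry: W=32, H=8, L=9, patches (4, 3) -> 18 tokens."""
    base = dict(
        W=32, H=8, N=6, L=9, p1=4, p2=3, D=16, n_layers=2, n_heads=2,
        ff_dim=32, dropout=0.0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
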