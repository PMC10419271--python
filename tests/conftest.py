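import numpy as np
import pytest

from netvb import (
    Connectome,
    FitParams,
    NeuralMassConstants,
    SimConfig,
    gen_connectome,
)


@pytest.fixture(scope="session")
def small_connectome() -> Connectome:
    """Fully connected 6-node synthetic connectome, max-one normalized."""
    return gen_connectome(6, density=1.0, seed=0)


@pytest.fixture(scope="session")
def default_params() -> FitParams:
    """Parameter point in the low-firing noise-driven regime."""
    return FitParams(G=1.5, J_NMDA=0.15, w_plus=1.4, J_i=3.2)


@pytest.fixture
def short_cfg() -> SimConfig:
    """Short simulation for unit tests (50 s recorded)."""
    return SimConfig(duration=60.0, transient=10.0, seed=7)


@pytest.fixture
def noiseless() -> NeuralMassConstants:
    return NeuralMassConstants(sigma=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
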