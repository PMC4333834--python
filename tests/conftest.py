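import numpy as np
import pytest

from ramshorn import Composition, ModelParams, params_from_energies
from ramshorn.landscape import Landscape


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """Reference parameters: Ems = 8 kBT, Emb = 7 kBT (deltaE = 1), N = 32."""
    return ModelParams()


@pytest.fixture(scope="session")
def all_d32() -> Composition:
    return Composition("D" * 32)


def make_params(Ems: float, Emb: float, N: int = 32, **kw) -> ModelParams:
    return params_from_energies(Ems, Emb, ModelParams(N=N, **kw))


@pytest.fixture()
def flat_landscape() -> Landscape:
    x = np.arange(0.0, 301.0, 2.0)
    return Landscape(x, np.zeros_like(x))


@pytest.fixture()
def linear_landscape() -> Landscape:
    x = np.arange(0.0, 301.0, 2.0)
    return Landscape(x, 0.02 * x)


@pytest.fixture()
def cosine_landscape() -> Landscape:
    """F = 2 cos(2 pi Rx / 125.66): minima at 62.83 + k*125.66 nm."""
    x = np.arange(0.0, 301.0, 1.0)
    return Landscape(x, 2.0 * np.cos(2 * np.pi * x / 125.66))
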