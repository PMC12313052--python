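import numpy as np
import pytest
from hypothesis import settings

from evoscreen import PottsModel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_model(L: int, q: int, seed: int, coupling_scale: float = 0.5) -> PottsModel:
    """Dense random Potts model with symmetric couplings."""
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"[:q]
    h = rng.normal(0, 1, size=(L, q))
    J = rng.normal(0, coupling_scale, size=(L, L, q, q))
    J = (J + J.transpose(1, 0, 3, 2)) / 2
    J[np.arange(L), np.arange(L)] = 0.0
    wt = "".join(alphabet[i] for i in rng.integers(0, q, size=L))
    return PottsModel(h=h, J=J, wt_sequence=wt, alphabet=alphabet)


@pytest.fixture
def small_model() -> PottsModel:
    return random_model(L=5, q=4, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
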