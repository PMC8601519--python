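import numpy as np
import pytest

from frustnet import SignedNetwork


def make_random_signed(
    n: int,
    rng: np.random.Generator,
    p_present: float = 1.0,
    p_neg: float = 0.3,
) -> SignedNetwork:
    """Random symmetric signed network with controllable sparsity and sign mix."""
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < p_present
    signs = np.where(rng.random(iu[0].size) < p_neg, -1, 1)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu] = np.where(present, signs, 0)
    a = a + a.T
    return SignedNetwork(a)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_signed():
    return make_random_signed
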