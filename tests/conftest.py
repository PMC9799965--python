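import numpy as np
import pytest

from chrononet.connectome import WeightedNetwork
from chrononet.parcellation import default_parcellation


@pytest.fixture
def parc12():
    """12 regions in 3 systems of 4, hemispheres split at the midpoint."""
    return default_parcellation(12, [("A", 4), ("B", 4), ("C", 4)])


@pytest.fixture
def parc40():
    """40 regions in 4 systems of 10 (the scaled cohort geometry)."""
    return default_parcellation(40, [("A", 10), ("B", 10), ("C", 10), ("D", 10)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def weighted_from(z: np.ndarray, **meta) -> WeightedNetwork:
    z = np.asarray(z, float)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return WeightedNetwork(z, meta=meta)


@pytest.fixture
def random_weighted(rng):
    def make(n: int, seed=None) -> WeightedNetwork:
        r = np.random.default_rng(seed) if seed is not None else rng
        z = np.abs(r.normal(size=(n, n)))
        return weighted_from(z)

    return make
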