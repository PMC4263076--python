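import numpy as np
import pytest

import brainglass as bg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Small but well-separated modular synthetic model."""
    return bg.SyntheticModelSpec(
        n_sites=120, n_modules=4, n_timepoints=400, seed=7
    )


@pytest.fixture(scope="session")
def small_sites(small_spec):
    return bg.generate_sites(small_spec)


@pytest.fixture(scope="session")
def small_graph(small_spec, small_sites):
    tc = bg.generate_modular_bold(small_spec, small_sites)
    C = bg.pairwise_correlation(tc)
    return bg.build_interaction_graph(C, 16)


@pytest.fixture
def pair_graph():
    """Two mutually coupled spins."""
    return np.array([[0, 1], [1, 0]], dtype=np.int8)


def symmetric_random_adjacency(n: int, p: float, seed: int) -> np.ndarray:
    """Erdos-Renyi-style symmetric binary adjacency, zero diagonal."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = 1
    return A


def pair_energy(A: np.ndarray, S: np.ndarray) -> float:
    """E(S) = -1/4 sum over unordered coupled pairs of S_i S_k.

    For a symmetric adjacency this is the potential whose single-flip
    differences equal the model's activation energy dE_i.
    """
    return -0.125 * float(S @ A @ S)
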