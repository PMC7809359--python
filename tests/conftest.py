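import numpy as np
import pytest

from dendroprune import (
    make_cayley,
    make_chain,
    make_demo_pyramidal,
    make_random_tree,
    make_star,
)


@pytest.fixture(scope="session")
def demo_neuron():
    """Deterministic pyramidal-like morphology (228 dendritic compartments)."""
    return make_demo_pyramidal()


@pytest.fixture
def chain5():
    return make_chain(5, soma="end")


def batch_mean_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Standard error of the mean of an autocorrelated 0/1 series via
    batch means."""
    n = len(x) // n_batches * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
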