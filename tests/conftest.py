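import numpy as np
import pytest

from netprior import (
    BetaSourceParams,
    ConfidenceMatrix,
    DirectedNetwork,
    random_walk_subnetwork,
    scale_free_seed_graph,
    simulate_sources,
)


def labels(m: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(m))


def random_confidence(rng: np.random.Generator, m: int, name: str = "src") -> ConfidenceMatrix:
    vals = rng.random((m, m))
    np.fill_diagonal(vals, 0.0)
    return ConfidenceMatrix(labels(m), vals, name)


def random_truth(rng: np.random.Generator, m: int, require_dag: bool = False) -> DirectedNetwork:
    seed = scale_free_seed_graph(max(5 * m, 30), rng)
    return random_walk_subnetwork(seed, m, rng, require_dag=require_dag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_truth(rng):
    """A 3-node, 2-edge truth network with two informative simulated sources."""
    truth = DirectedNetwork(labels(3), np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]))
    params = BetaSourceParams([5.0, 5.0], [5.0, 5.0])
    thetas = simulate_sources(truth, params, rng)
    return truth, params, thetas
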