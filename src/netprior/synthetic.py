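"""Generators for every input the validation protocol needs.

Ground-truth networks are sampled as random-walk subnetworks of larger seed
graphs, mimicking the extraction of pathway neighbourhoods from a curated
signalling-pathway collection.  Information sources are simulated from the
ground truth by drawing edge confidences from Beta distributions — present
edges from Beta(alpha_k, 1), absent edges from Beta(1, beta_k) under the
default asymmetric form — so that large shape parameters mean a sharp,
informative source and alpha = beta = 1 means a source that carries no signal
at all.  A pure-noise source (uniform confidences) and a shortest-path
distance source are also provided, plus multinomial data simulation from DAGs
for the structure-learning experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    EPS,
    BetaSourceParams,
    ConfidenceMatrix,
    DirectedNetwork,
)


@dataclass
class SimulationDesign:
    """Parameters of one simulation study cell."""

    m: int = 20
    n_sources: int = 5
    alpha: float = 10.0
    beta: float = 10.0
    n_samples: int = 100
    n_categories: int = 3
    replicates: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_sources < 1:
            raise ValueError("need at least one source")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")


def scale_free_seed_graph(
    n: int, rng: np.random.Generator, attachment: int = 2
) -> DirectedNetwork:
    """Preferential-attachment digraph used as a stand-in pathway collection.

    An undirected Barabasi–Albert graph (``attachment`` links per new node,
    hence a connected skeleton with heavy-tailed degrees) whose edges are
    oriented uniformly at random, giving mean out-degree about ``attachment``.
    """
    if n < 5:
        raise ValueError("seed graph needs at least 5 nodes")
    if not 1 <= attachment < n:
        raise ValueError("attachment must be in [1, n)")
    g = nx.barabasi_albert_graph(n, attachment, seed=int(rng.integers(2**31)))
    labels = tuple(f"n{i}" for i in range(n))
    adj = np.zeros((n, n), dtype=np.int8)
    for u, v in g.edges():
        if rng.random() < 0.5:
            u, v = v, u
        adj[u, v] = 1
    return DirectedNetwork(labels, adj)


def random_walk_subnetwork(
    seed_graph: DirectedNetwork,
    m: int,
    rng: np.random.Generator,
    require_dag: bool = False,
    max_attempts: int = 1000,
) -> DirectedNetwork:
    """Sample an m-node ground-truth network by random walk on a seed graph.

    The walk runs on the *undirected* skeleton (directed walks dead-end in
    signalling topologies) from a uniformly chosen start node until m distinct
    nodes have been visited; the induced *directed* subgraph on those nodes is
    returned.  With ``require_dag`` the sampling is repeated until the induced
    subgraph is acyclic.
    """
    if m < 2 or m > seed_graph.m:
        raise ValueError("m must be between 2 and the seed-graph size")
    und = seed_graph.to_networkx().to_undirected()
    comps = [c for c in nx.connected_components(und) if len(c) >= m]
    if not comps:
        raise ValueError(f"no undirected component with >= {m} nodes")
    starts = sorted(set().union(*comps))
    adj_full = seed_graph.adjacency
    index = {lab: i for i, lab in enumerate(seed_graph.node_labels)}
    neighbours = {u: sorted(und.neighbors(u)) for u in und.nodes}

    for _ in range(max_attempts):
        current = starts[int(rng.integers(len(starts)))]
        visited: list[str] = [current]
        seen = {current}
        while len(visited) < m:
            nbrs = neighbours[current]
            current = nbrs[int(rng.integers(len(nbrs)))]
            if current not in seen:
                seen.add(current)
                visited.append(current)
        idx = [index[u] for u in visited]
        sub = DirectedNetwork(tuple(visited), adj_full[np.ix_(idx, idx)])
        if not require_dag or sub.is_dag:
            return sub
    raise RuntimeError(f"no acyclic subnetwork found in {max_attempts} attempts")


def simulate_sources(
    omega: DirectedNetwork,
    params: BetaSourceParams,
    rng: np.random.Generator,
    form: str = "asymmetric",
) -> list[ConfidenceMatrix]:
    """Draw K edge-confidence matrices from the generative Beta model.

    Asymmetric form (default): confidences of present edges ~ Beta(alpha_k, 1)
    (mean alpha/(alpha+1), near 1 for large alpha), of absent edges
    ~ Beta(1, beta_k) (near 0 for large beta).  Mirrored form: Beta(alpha_k,
    beta_k) for present, Beta(beta_k, alpha_k) for absent edges.
    """
    if form not in ("asymmetric", "mirrored"):
        raise ValueError(f"unknown likelihood form: {form}")
    m = omega.m
    present = omega.adjacency.astype(bool)
    off = ~np.eye(m, dtype=bool)
    out = []
    for k in range(params.n_sources):
        a, b = params.alpha[k], params.beta[k]
        if form == "asymmetric":
            vals = rng.beta(1.0, b, size=(m, m))
            vals[present] = rng.beta(a, 1.0, size=int(present.sum()))
        else:
            vals = rng.beta(b, a, size=(m, m))
            vals[present] = rng.beta(a, b, size=int(present.sum()))
        vals[~off] = 0.0
        out.append(ConfidenceMatrix(omega.node_labels, vals, f"source_{k}"))
    return out


def noise_source(
    m_or_labels, rng: np.random.Generator, name: str = "noise"
) -> ConfidenceMatrix:
    """An uninformative source: off-diagonal cells i.i.d. uniform on (0, 1)."""
    if isinstance(m_or_labels, int):
        labels = tuple(f"n{i}" for i in range(m_or_labels))
    else:
        labels = tuple(m_or_labels)
    m = len(labels)
    if m < 2:
        raise ValueError("need at least 2 nodes")
    vals = rng.random((m, m))
    np.fill_diagonal(vals, 0.0)
    return ConfidenceMatrix(labels, vals, name)


def confidence_from_network_distance(
    net: DirectedNetwork,
    mapping: str = "inverse",
    decay: float = 1.0,
    epsilon: float = EPS,
) -> ConfidenceMatrix:
    """Turn directed shortest-path distances into edge confidences.

    ``mapping="inverse"`` (default) uses theta_ij = 1/d_ij, so direct edges
    (d=1) map to the top of the scale and two-hop pairs to 0.5;
    ``mapping="exponential"`` uses exp(-decay * (d - 1)).  Unreachable pairs
    get ``epsilon``; the result is clipped into [epsilon, 1 - epsilon].
    """
    if mapping not in ("inverse", "exponential"):
        raise ValueError(f"unknown distance mapping: {mapping}")
    g = net.to_networkx()
    m = net.m
    index = {lab: i for i, lab in enumerate(net.node_labels)}
    vals = np.full((m, m), epsilon)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        i = index[src]
        for tgt, d in dists.items():
            if tgt == src:
                continue
            j = index[tgt]
            vals[i, j] = 1.0 / d if mapping == "inverse" else np.exp(-decay * (d - 1))
    vals = np.clip(vals, epsilon, 1.0 - epsilon)
    np.fill_diagonal(vals, 0.0)
    return ConfidenceMatrix(net.node_labels, vals, "network_distance")


def simulate_cpts(
    dag: DirectedNetwork, n_categories: int, rng: np.random.Generator
) -> dict[int, tuple[tuple[int, ...], np.ndarray]]:
    """Draw conditional probability tables for every node of a DAG.

    Returns ``{node_index: (parent_indices, table)}`` where ``table`` has one
    row per joint parent configuration (parents in ascending index order, the
    first parent varying slowest) and each row is a category distribution
    drawn from a flat Dirichlet.
    """
    if not dag.is_dag:
        raise ValueError("conditional tables require an acyclic graph")
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    cpts = {}
    for v in range(dag.m):
        parents = tuple(int(p) for p in np.nonzero(dag.adjacency[:, v])[0])
        q = n_categories ** len(parents)
        table = rng.dirichlet(np.ones(n_categories), size=q)
        cpts[v] = (parents, table)
    return cpts


def simulate_categorical_data(
    dag: DirectedNetwork,
    cpts: dict[int, tuple[tuple[int, ...], np.ndarray]],
    n: int,
    rng: np.random.Generator,
):
    """Ancestral sampling: n i.i.d. multinomial samples in topological order."""
    from .bn import CategoricalDataset

    if n < 1:
        raise ValueError("need at least one sample")
    order = list(nx.topological_sort(dag.to_networkx()))
    index = {lab: i for i, lab in enumerate(dag.node_labels)}
    m = dag.m
    r = cpts[0][1].shape[1]
    data = np.zeros((n, m), dtype=np.int64)
    for lab in order:
        v = index[lab]
        parents, table = cpts[v]
        if parents:
            config = np.zeros(n, dtype=np.int64)
            for p in parents:  # first parent varies slowest
                config = config * r + data[:, p]
        else:
            config = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(table, axis=1)
        u = rng.random(n)
        data[:, v] = (u[:, None] > cum[config]).sum(axis=1)
    return CategoricalDataset(dag.node_labels, [r] * m, data)
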