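"""Shared domain types: directed networks, edge-confidence matrices, consensus priors.

Conventions used throughout the package:

* adjacency / confidence entry ``(i, j)`` refers to the directed edge ``i -> j``;
* self-edges are structurally excluded — diagonals are stored as 0 and ignored
  by every consumer;
* consensus priors are clipped into ``[EPS, 1 - EPS]`` before any logarithm is
  taken, so that log-scale structure scores stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

#: Default clipping width for prior probabilities before log-scale use.
EPS = 1e-6


class PriorMethod(str, Enum):
    """Identifier of the combiner that produced a consensus prior."""

    LFM = "LFM"
    NOM = "NOM"
    NOM_RNK = "NOM.RNK"
    IP = "IP"
    IP_RNK = "IP.RNK"
    MP = "MP"
    MP_RNK = "MP.RNK"
    CONSTANT = "CONSTANT"


def _check_labels(labels) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise ValueError("node labels must be unique")
    return labels


@dataclass
class DirectedNetwork:
    """A directed graph over labeled nodes, stored as a binary adjacency matrix.

    Entry ``adjacency[i, j] == 1`` means there is a directed edge from node
    ``node_labels[i]`` to ``node_labels[j]``.  Serves both as ground-truth
    network and as the output of structure learning.
    """

    node_labels: tuple[str, ...]
    adjacency: np.ndarray
    _is_dag: bool | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_labels = _check_labels(self.node_labels)
        adj = np.asarray(self.adjacency)
        m = len(self.node_labels)
        if adj.shape != (m, m):
            raise ValueError(
                f"adjacency shape {adj.shape} does not match {m} node labels"
            )
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = adj.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def is_dag(self) -> bool:
        if self._is_dag is None:
            self._is_dag = is_acyclic(self)
        return self._is_dag

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.adjacency)
        return [(self.node_labels[i], self.node_labels[j]) for i, j in zip(ii, jj)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(
        cls, node_labels, edges: list[tuple[str, str]]
    ) -> "DirectedNetwork":
        labels = _check_labels(node_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v} is not allowed")
            adj[index[u], index[v]] = 1
        return cls(labels, adj)


@dataclass
class ConfidenceMatrix:
    """One information source rendered as an m x m matrix of edge confidences.

    Off-diagonal entries lie in the closed interval [0, 1]; the diagonal is
    meaningless and stored as 0.
    """

    node_labels: tuple[str, ...]
    values: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        self.node_labels = _check_labels(self.node_labels)
        vals = np.asarray(self.values, dtype=float)
        m = len(self.node_labels)
        if vals.shape != (m, m):
            raise ValueError(f"values shape {vals.shape} does not match {m} labels")
        self.values = vals

    @property
    def m(self) -> int:
        return len(self.node_labels)


@dataclass
class ConsensusPrior:
    """The combined matrix B of prior edge beliefs fed to structure learning."""

    node_labels: tuple[str, ...]
    values: np.ndarray
    method: PriorMethod

    def __post_init__(self) -> None:
        self.node_labels = _check_labels(self.node_labels)
        vals = np.asarray(self.values, dtype=float)
        m = len(self.node_labels)
        if vals.shape != (m, m):
            raise ValueError(f"values shape {vals.shape} does not match {m} labels")
        off = ~np.eye(m, dtype=bool)
        if not np.isfinite(vals[off]).all():
            raise ValueError("prior entries must be finite")
        if (vals[off] < 0).any() or (vals[off] > 1).any():
            raise ValueError("prior entries must lie in [0, 1]")
        vals = vals.copy()
        np.fill_diagonal(vals, 0.0)
        self.values = vals
        self.method = PriorMethod(self.method)

    @property
    def m(self) -> int:
        return len(self.node_labels)


@dataclass
class BetaSourceParams:
    """Per-source Beta shape parameters (alpha_k, beta_k), one pair per source."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("alpha and beta must be 1-d vectors of equal length")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("parameters must be finite")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("parameters must be strictly positive")
        self.alpha = a
        self.beta = b

    @property
    def n_sources(self) -> int:
        return len(self.alpha)


def validate_confidence_matrix(matrix: ConfidenceMatrix) -> ConfidenceMatrix:
    """Validate entry ranges and zero the diagonal of a confidence matrix.

    Raises ``ValueError`` on non-finite entries or off-diagonal values outside
    [0, 1].  Diagonal entries are overwritten with 0 (the diagonal carries no
    information; self-edges are excluded by convention).
    """
    vals = matrix.values
    m = matrix.m
    off = ~np.eye(m, dtype=bool)
    bad = ~np.isfinite(vals[off])
    if bad.any():
        raise ValueError(f"{matrix.source_name or 'matrix'}: non-finite entry")
    out = (vals[off] < 0) | (vals[off] > 1)
    if out.any():
        i, j = [c[0] for c in np.nonzero(off & ((vals < 0) | (vals > 1)))]
        raise ValueError(
            f"{matrix.source_name or 'matrix'}: entry outside [0,1] at "
            f"({matrix.node_labels[i]}, {matrix.node_labels[j]}): {vals[i, j]}"
        )
    clean = vals.copy()
    np.fill_diagonal(clean, 0.0)
    return ConfidenceMatrix(matrix.node_labels, clean, matrix.source_name)


def clip_prior(values: np.ndarray, epsilon: float = EPS) -> np.ndarray:
    """Clip off-diagonal entries into ``[epsilon, 1 - epsilon]``.

    Entries already inside the band are unchanged, so ordering is preserved.
    The diagonal is left at 0.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    vals = np.asarray(values, dtype=float).copy()
    off = ~np.eye(vals.shape[0], dtype=bool)
    vals[off] = np.clip(vals[off], epsilon, 1.0 - epsilon)
    return vals


def is_acyclic(net: DirectedNetwork) -> bool:
    """True iff the network contains no directed cycle (Kahn peeling)."""
    adj = net.adjacency
    indeg = adj.sum(axis=0).astype(int)
    stack = [i for i in range(net.m) if indeg[i] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in np.nonzero(adj[u])[0]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(int(v))
    return seen == net.m


def check_same_labels(objs) -> tuple[str, ...]:
    """Require that all matrices/networks share the same ordered label set."""
    objs = list(objs)
    if not objs:
        raise ValueError("need at least one input")
    labels = objs[0].node_labels
    for o in objs[1:]:
        if o.node_labels != labels:
            raise ValueError("node label mismatch between inputs")
    return labels
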