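"""Categorical Bayesian-network structure learning with a Bernoulli edge prior.

Structures are scored by the BIC-penalised multinomial log-likelihood plus an
edge-wise Bernoulli structure prior

    log P(G) = sum_{i != j} [ G_ij log B_ij + (1 - G_ij) log(1 - B_ij) ],

where B is a consensus prior matrix.  Because both the BIC and the prior
decompose over (child, parent-set) families, the globally optimal DAG under a
maximum-parents constraint can be found by the classic two-stage dynamic
programme (best parent set per node per candidate subset, then best sink
ordering over node subsets).  A greedy hill climber with restarts serves as
the scalable fallback, and a brute-force enumerator over all DAGs is kept as
an independent oracle for small problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import ConsensusPrior, DirectedNetwork, _check_labels, clip_prior


@dataclass
class CategoricalDataset:
    """n samples of m categorical variables with small integer levels."""

    variable_labels: tuple[str, ...]
    levels: list[int]
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.variable_labels = _check_labels(self.variable_labels)
        rows = np.asarray(self.rows)
        m = len(self.variable_labels)
        if rows.ndim != 2 or rows.shape[1] != m:
            raise ValueError(f"rows shape {rows.shape} does not match {m} variables")
        if rows.shape[0] < 1:
            raise ValueError("need at least one sample")
        self.levels = [int(r) for r in self.levels]
        if len(self.levels) != m or any(r < 2 for r in self.levels):
            raise ValueError("each variable needs >= 2 levels")
        if not np.issubdtype(rows.dtype, np.integer):
            raise ValueError("data must be integer-coded")
        for j, r in enumerate(self.levels):
            col = rows[:, j]
            if (col < 0).any() or (col >= r).any():
                raise ValueError(f"values of variable {j} outside [0, {r})")
        self.rows = rows.astype(np.int64)

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def m(self) -> int:
        return len(self.variable_labels)


def family_bic(data: CategoricalDataset, child: int, parents) -> float:
    """BIC-penalised maximum log-likelihood of one (child | parents) family.

    ``sum_{c,k} n_ck log(n_ck / n_c) - (1/2) log(n) (r_child - 1) prod_p r_p``
    with empty parent configurations contributing nothing.
    """
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError("child cannot be its own parent")
    rows = data.rows
    r = data.levels[child]
    q = 1
    config = np.zeros(data.n, dtype=np.int64)
    for p in parents:
        config = config * data.levels[p] + rows[:, p]
        q *= data.levels[p]
    codes = config * r + rows[:, child]
    n_ck = np.bincount(codes, minlength=q * r).reshape(q, r)
    n_c = n_ck.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_ck * np.log(np.where(n_ck > 0, n_ck / np.where(n_c > 0, n_c, 1), 1.0))
    loglik = float(terms[n_ck > 0].sum())
    penalty = 0.5 * np.log(data.n) * (r - 1) * q
    return loglik - penalty


def structure_log_prior(graph: DirectedNetwork, prior: ConsensusPrior) -> float:
    """Bernoulli log prior of a graph: each potential edge present w.p. B_ij."""
    if graph.node_labels != prior.node_labels:
        raise ValueError("node label mismatch between graph and prior")
    b = clip_prior(prior.values)
    off = ~np.eye(graph.m, dtype=bool)
    g = graph.adjacency[off].astype(float)
    bb = b[off]
    return float((g * np.log(bb) + (1 - g) * np.log1p(-bb)).sum())


def _prior_terms(prior: ConsensusPrior | None, m: int) -> tuple[np.ndarray, float]:
    """Per-edge log-odds and graph-independent constant of the structure prior.

    ``None`` means the uninformative B = 0.5 prior, whose log-odds vanish.
    """
    if prior is None:
        return np.zeros((m, m)), m * (m - 1) * np.log(0.5)
    b = clip_prior(prior.values)
    off = ~np.eye(m, dtype=bool)
    odds = np.zeros((m, m))
    odds[off] = np.log(b[off]) - np.log1p(-b[off])
    const = float(np.log1p(-b[off]).sum())
    return odds, const


def _family_score_tables(
    data: CategoricalDataset, prior: ConsensusPrior | None, max_parents: int
) -> list[dict[int, float]]:
    """Per-node map from parent-set bitmask to BIC-plus-prior family score."""
    m = data.m
    odds, _ = _prior_terms(prior, m)
    tables: list[dict[int, float]] = []
    for v in range(m):
        others = [u for u in range(m) if u != v]
        tab: dict[int, float] = {}
        for size in range(min(max_parents, m - 1) + 1):
            for ps in combinations(others, size):
                mask = 0
                for p in ps:
                    mask |= 1 << p
                tab[mask] = family_bic(data, v, ps) + sum(odds[p, v] for p in ps)
        tables.append(tab)
    return tables


def _mask_to_parents(mask: int, m: int) -> tuple[int, ...]:
    return tuple(p for p in range(m) if mask >> p & 1)


def exact_search(
    data: CategoricalDataset,
    prior: ConsensusPrior | None = None,
    max_parents: int = 5,
) -> DirectedNetwork:
    """Globally optimal DAG under the BIC + Bernoulli-prior score.

    Dynamic programming over node subsets (best parent set per candidate
    subset, then best sink ordering); exact given the ``max_parents``
    constraint.  For m > 14 the subset lattice is too large and the search
    falls back to hill climbing with default restarts.  Ties are broken
    deterministically (first-best in ascending parent-set bitmask order,
    which prefers smaller/lexicographically earlier parent sets).
    """
    m = data.m
    if m > 14:
        return hill_climb(data, prior, max_parents, rng=np.random.default_rng(0))
    local = _family_score_tables(data, prior, max_parents)

    full = 1 << m
    best_ps_score = [np.full(full, -np.inf) for _ in range(m)]
    best_ps_mask = [np.zeros(full, dtype=np.int64) for _ in range(m)]
    for v in range(m):
        score_v, mask_v = best_ps_score[v], best_ps_mask[v]
        vbit = 1 << v
        for s in range(full):
            if s & vbit:
                continue
            best, barg = -np.inf, 0
            direct = local[v].get(s)
            if direct is not None:
                best, barg = direct, s
            sub = s
            while sub:
                low = sub & -sub
                cand = score_v[s ^ low]
                if cand > best:
                    best, barg = cand, int(mask_v[s ^ low])
                sub ^= low
            score_v[s], mask_v[s] = best, barg

    net_score = np.full(full, -np.inf)
    net_score[0] = 0.0
    choice = np.zeros(full, dtype=np.int64)  # sink node chosen for each subset
    for s in range(1, full):
        best, barg = -np.inf, -1
        sub = s
        while sub:
            low = sub & -sub
            v = low.bit_length() - 1
            rest = s ^ low
            cand = net_score[rest] + best_ps_score[v][rest]
            if cand > best:
                best, barg = cand, v
            sub ^= low
        net_score[s], choice[s] = best, barg

    adj = np.zeros((m, m), dtype=np.int8)
    s = full - 1
    while s:
        v = int(choice[s])
        rest = s ^ (1 << v)
        for p in _mask_to_parents(int(best_ps_mask[v][rest]), m):
            adj[p, v] = 1
        s = rest
    return DirectedNetwork(data.variable_labels, adj)


def network_score(
    data: CategoricalDataset,
    net: DirectedNetwork,
    prior: ConsensusPrior | None = None,
) -> float:
    """Total BIC-plus-prior score of a given DAG (sum of family BICs + log prior)."""
    if net.node_labels != data.variable_labels:
        raise ValueError("label mismatch between data and network")
    total = 0.0
    for v in range(data.m):
        parents = tuple(int(p) for p in np.nonzero(net.adjacency[:, v])[0])
        total += family_bic(data, v, parents)
    if prior is None:
        total += data.m * (data.m - 1) * np.log(0.5)
    else:
        total += structure_log_prior(net, prior)
    return total


def brute_force_search(
    data: CategoricalDataset,
    prior: ConsensusPrior | None = None,
    max_parents: int = 5,
) -> tuple[DirectedNetwork, float]:
    """Exhaustive enumeration of every DAG — independent oracle for small m.

    Scores each acyclic digraph directly (no dynamic programming, no shared
    score tables beyond per-family BIC caching) and returns the best DAG and
    its score.  Limited to m <= 5.
    """
    m = data.m
    if m > 5:
        raise ValueError("brute force limited to m <= 5")
    cells = [(i, j) for i in range(m) for j in range(m) if i != j]
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def fam(v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        if key not in cache:
            cache[key] = family_bic(data, v, parents)
        return cache[key]

    odds, const = _prior_terms(prior, m)
    best_net, best_score = None, -np.inf
    for mask in range(1 << len(cells)):
        adj = np.zeros((m, m), dtype=np.int8)
        for b, (i, j) in enumerate(cells):
            if mask >> b & 1:
                adj[i, j] = 1
        if (adj.sum(axis=0) > max_parents).any():
            continue
        net = DirectedNetwork(data.variable_labels, adj)
        if not net.is_dag:
            continue
        score = const
        for v in range(m):
            parents = tuple(int(p) for p in np.nonzero(adj[:, v])[0])
            score += fam(v, parents) + sum(odds[p, v] for p in parents)
        if score > best_score:
            best_net, best_score = net, score
    return best_net, float(best_score)


def _has_path(adj: np.ndarray, src: int, dst: int) -> bool:
    """Directed reachability by DFS (used for acyclicity-preserving moves)."""
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in np.nonzero(adj[u])[0]:
            if v not in seen:
                seen.add(int(v))
                stack.append(int(v))
    return False


def hill_climb(
    data: CategoricalDataset,
    prior: ConsensusPrior | None = None,
    max_parents: int = 5,
    restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> DirectedNetwork:
    """Greedy add/delete/reverse search on the BIC-plus-prior score.

    The first restart starts from the empty graph, later ones from random
    DAGs; the best local optimum across restarts is returned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = data.m
    odds, _ = _prior_terms(prior, m)
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def fam(v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        if key not in cache:
            cache[key] = family_bic(data, v, parents) + sum(odds[p, v] for p in parents)
        return cache[key]

    def parents_of(adj, v) -> tuple[int, ...]:
        return tuple(int(p) for p in np.nonzero(adj[:, v])[0])

    def run(adj: np.ndarray) -> tuple[np.ndarray, float]:
        fam_sc = [fam(v, parents_of(adj, v)) for v in range(m)]
        while True:
            best_delta, best_move = 1e-9, None
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    if adj[i, j]:
                        ps = parents_of(adj, j)
                        without = tuple(p for p in ps if p != i)
                        delta = fam(j, without) - fam_sc[j]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", i, j)
                        # reversal: remove i->j, add j->i
                        if not adj[j, i] and len(parents_of(adj, i)) < max_parents:
                            adj[i, j] = 0
                            ok = not _has_path(adj, i, j)
                            adj[i, j] = 1
                            if ok:
                                psi = parents_of(adj, i)
                                delta = (
                                    fam(j, without)
                                    - fam_sc[j]
                                    + fam(i, tuple(sorted(psi + (j,))))
                                    - fam_sc[i]
                                )
                                if delta > best_delta:
                                    best_delta, best_move = delta, ("rev", i, j)
                    else:
                        ps = parents_of(adj, j)
                        if len(ps) >= max_parents or _has_path(adj, j, i):
                            continue
                        delta = fam(j, tuple(sorted(ps + (i,)))) - fam_sc[j]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", i, j)
            if best_move is None:
                break
            kind, i, j = best_move
            if kind == "add":
                adj[i, j] = 1
            elif kind == "del":
                adj[i, j] = 0
            else:
                adj[i, j] = 0
                adj[j, i] = 1
                fam_sc[i] = fam(i, parents_of(adj, i))
            fam_sc[j] = fam(j, parents_of(adj, j))
        return adj, float(sum(fam_sc))

    def random_dag() -> np.ndarray:
        order = rng.permutation(m)
        adj = np.zeros((m, m), dtype=np.int8)
        for b in range(1, m):
            for a in range(b):
                if rng.random() < 0.2 and adj[:, order[b]].sum() < max_parents:
                    adj[order[a], order[b]] = 1
        return adj

    best_adj, best_score = None, -np.inf
    for r in range(max(1, restarts)):
        start = np.zeros((m, m), dtype=np.int8) if r == 0 else random_dag()
        adj, score = run(start)
        if score > best_score:
            best_adj, best_score = adj.copy(), score
    return DirectedNetwork(data.variable_labels, best_adj)
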