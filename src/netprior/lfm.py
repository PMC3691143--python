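"""Latent Factor Model: joint MCMC over a hidden network and per-source Beta parameters.

The model assumes every information source's confidence matrix Theta_k was
generated from one hidden true network Omega: confidences of truly present
edges follow Beta(alpha_k, 1) and of absent edges Beta(1, beta_k) (the
default *asymmetric* form; a *mirrored* Beta(alpha_k, beta_k) /
Beta(beta_k, alpha_k) form is available).  Large shape parameters mean the
source separates present from absent edges sharply; alpha_k = beta_k = 1
makes the source's likelihood flat, i.e. the source carries no weight.
Joint posterior inference over Omega and all (alpha_k, beta_k) therefore
weights sources automatically: a pure-noise source is driven toward
parameters near 1 and effectively filtered out.

Inference is an adaptive Metropolis–Hastings chain.  Network moves are edge
insertion, deletion and reversal, drawn uniformly from the currently valid
moves; parameters move jointly on log-scale with a multivariate Gaussian
kernel whose covariance starts at the identity and is periodically refreshed
from the empirical covariance of the sampled log-parameters (scaled by
2.38^2/d, plus a small jitter).  The consensus prior is the posterior edge
inclusion frequency matrix.

Because the Beta likelihood factorises over matrix cells, the chain keeps
per-source sufficient statistics (sums of log theta and log(1-theta) over
present cells), making a structure move O(1) and a parameter move closed
form regardless of network size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, logsumexp

from .core import (
    BetaSourceParams,
    ConfidenceMatrix,
    ConsensusPrior,
    DirectedNetwork,
    PriorMethod,
    check_same_labels,
    clip_prior,
    validate_confidence_matrix,
)


@dataclass
class LFMConfig:
    """Chain-length, prior and proposal settings for the latent factor model.

    Defaults follow the reference protocol (burn-in 100000, 500000 sampling
    iterations, a parameter move every 10th iteration, covariance adaptation
    every 100th parameter move); test and benchmark runs shorten the chain
    via these fields.
    """

    burn_in: int = 100_000
    samples: int = 500_000
    param_move_period: int = 10
    cov_update_period: int = 100
    edge_prior_rho: float = 0.05
    param_bounds: tuple[float, float] = (0.1, 1000.0)
    rng_seed: int = 0
    likelihood_form: str = "asymmetric"
    fix_params: bool = False
    init_alpha: float = 1.0
    init_beta: float = 1.0
    trace_every: int = 1000

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.samples <= 0:
            raise ValueError("burn_in and samples must be positive")
        lo, hi = self.param_bounds
        if not (0 < lo < hi):
            raise ValueError("param_bounds must be ordered and positive")
        if not 0 < self.edge_prior_rho < 1:
            raise ValueError("edge_prior_rho must lie in (0, 1)")
        if self.likelihood_form not in ("asymmetric", "mirrored"):
            raise ValueError(f"unknown likelihood form: {self.likelihood_form}")


@dataclass
class MCMCTrace:
    """Posterior summaries and bookkeeping from one chain."""

    edge_frequency: np.ndarray
    param_samples: np.ndarray          # rows of (log alpha_1..K, log beta_1..K)
    param_sample_iters: np.ndarray
    acceptance_rates: dict[str, float]
    log_posterior_trace: np.ndarray
    log_posterior_iters: np.ndarray
    burn_in: int = 0

    def posterior_mean_params(self) -> BetaSourceParams:
        """Posterior means of alpha_k and beta_k over post-burn-in samples."""
        if len(self.param_samples) == 0:
            raise ValueError("no parameter samples recorded (fixed parameters?)")
        keep = self.param_sample_iters >= self.burn_in
        z = np.exp(self.param_samples[keep])
        k = z.shape[1] // 2
        means = z.mean(axis=0)
        return BetaSourceParams(means[:k], means[k:])


def _check_theta_open(theta: np.ndarray, m: int) -> None:
    off = ~np.eye(m, dtype=bool)
    v = theta[off]
    if (v <= 0).any() or (v >= 1).any():
        raise ValueError("confidences must lie strictly inside (0, 1); clip first")


def source_log_likelihood(
    theta: ConfidenceMatrix,
    omega: DirectedNetwork,
    alpha_k: float,
    beta_k: float,
    form: str = "asymmetric",
) -> float:
    """Log-likelihood of one source's confidences given a candidate network.

    Sums, over off-diagonal cells, the log Beta density of the observed
    confidence under the present-edge law when the cell is an edge of
    ``omega`` and the absent-edge law otherwise.
    """
    if alpha_k <= 0 or beta_k <= 0:
        raise ValueError("Beta parameters must be positive")
    check_same_labels([theta, omega])
    m = omega.m
    vals = theta.values
    _check_theta_open(vals, m)
    off = ~np.eye(m, dtype=bool)
    present = omega.adjacency.astype(bool) & off
    absent = off & ~present
    lt = np.log(vals, where=off, out=np.zeros_like(vals))
    lc = np.log1p(-vals, where=off, out=np.zeros_like(vals))
    if form == "asymmetric":
        ll_present = math.log(alpha_k) * present.sum() + (alpha_k - 1) * lt[present].sum()
        ll_absent = math.log(beta_k) * absent.sum() + (beta_k - 1) * lc[absent].sum()
    elif form == "mirrored":
        ll_present = (
            -betaln(alpha_k, beta_k) * present.sum()
            + (alpha_k - 1) * lt[present].sum()
            + (beta_k - 1) * lc[present].sum()
        )
        ll_absent = (
            -betaln(beta_k, alpha_k) * absent.sum()
            + (beta_k - 1) * lt[absent].sum()
            + (alpha_k - 1) * lc[absent].sum()
        )
    else:
        raise ValueError(f"unknown likelihood form: {form}")
    return float(ll_present + ll_absent)


def log_posterior(
    omega: DirectedNetwork,
    thetas: list[ConfidenceMatrix],
    params: BetaSourceParams,
    config: LFMConfig,
) -> float:
    """Unnormalised log posterior of (Omega, parameters) given the sources.

    Sum of the per-source Beta log-likelihoods, an independent Bernoulli(rho)
    prior on each potential edge, and a prior on the parameters that is flat
    on log-scale inside ``param_bounds`` (minus infinity outside).
    """
    lo, hi = config.param_bounds
    if ((params.alpha < lo) | (params.alpha > hi)).any():
        return -math.inf
    if ((params.beta < lo) | (params.beta > hi)).any():
        return -math.inf
    ll = sum(
        source_log_likelihood(
            th, omega, params.alpha[k], params.beta[k], config.likelihood_form
        )
        for k, th in enumerate(thetas)
    )
    rho = config.edge_prior_rho
    e = omega.n_edges
    n_cells = omega.m * (omega.m - 1)
    return ll + e * math.log(rho) + (n_cells - e) * math.log(1 - rho)


def count_structure_moves(adjacency: np.ndarray) -> int:
    """Number of valid single-edge moves: insertions + deletions + reversals."""
    m = adjacency.shape[0]
    n_cells = m * (m - 1)
    reversible = int(((adjacency == 1) & (adjacency.T == 0)).sum())
    return n_cells + reversible  # (n_cells - E) insertions + E deletions + R reversals


def propose_structure_move(
    omega: DirectedNetwork, rng: np.random.Generator
) -> tuple[DirectedNetwork, float]:
    """Draw one move uniformly from all valid insert/delete/reverse moves.

    Returns the proposed network and the log Hastings ratio
    ``log |moves(omega)| - log |moves(omega')|``.
    """
    adj = omega.adjacency.copy()
    m = omega.m
    present = [(int(i), int(j)) for i, j in zip(*np.nonzero(adj))]
    absent = [
        (i, j)
        for i in range(m)
        for j in range(m)
        if i != j and adj[i, j] == 0
    ]
    reversals = [(i, j) for (i, j) in present if adj[j, i] == 0]
    moves = (
        [("ins", c) for c in absent]
        + [("del", c) for c in present]
        + [("rev", c) for c in reversals]
    )
    kind, (i, j) = moves[int(rng.integers(len(moves)))]
    if kind == "ins":
        adj[i, j] = 1
    elif kind == "del":
        adj[i, j] = 0
    else:
        adj[i, j] = 0
        adj[j, i] = 1
    new = DirectedNetwork(omega.node_labels, adj)
    log_hr = math.log(len(moves)) - math.log(count_structure_moves(adj))
    return new, log_hr


def propose_param_move(
    params: BetaSourceParams,
    kernel_cov: np.ndarray,
    rng: np.random.Generator,
) -> BetaSourceParams:
    """Joint Gaussian random-walk step on (log alpha, log beta).

    The proposal is symmetric (Hastings ratio 1).  A non-positive-definite
    covariance falls back to the identity.
    """
    k = params.n_sources
    z = np.concatenate([np.log(params.alpha), np.log(params.beta)])
    try:
        chol = np.linalg.cholesky(kernel_cov)
    except np.linalg.LinAlgError:
        chol = np.eye(2 * k)
    zp = z + chol @ rng.standard_normal(2 * k)
    return BetaSourceParams(np.exp(zp[:k]), np.exp(zp[k:]))


def _stats_loglik(
    alpha: np.ndarray,
    beta: np.ndarray,
    n_edges: int,
    n_cells: int,
    sp_t: np.ndarray,
    sp_c: np.ndarray,
    tot_t: np.ndarray,
    tot_c: np.ndarray,
    form: str,
) -> float:
    """Total Beta log-likelihood from per-source sufficient statistics."""
    na = n_cells - n_edges
    if form == "asymmetric":
        ll = (
            n_edges * np.log(alpha)
            + (alpha - 1) * sp_t
            + na * np.log(beta)
            + (beta - 1) * (tot_c - sp_c)
        )
    else:
        ll = (
            -n_edges * betaln(alpha, beta)
            + (alpha - 1) * sp_t
            + (beta - 1) * sp_c
            - na * betaln(beta, alpha)
            + (beta - 1) * (tot_t - sp_t)
            + (alpha - 1) * (tot_c - sp_c)
        )
    return float(ll.sum())


def _gain_matrix(
    alpha: np.ndarray,
    beta: np.ndarray,
    lt: np.ndarray,
    lc: np.ndarray,
    rho: float,
    form: str,
) -> np.ndarray:
    """Per-cell change in log posterior when turning that cell's edge on."""
    if form == "asymmetric":
        const = float(np.log(alpha).sum() - np.log(beta).sum())
        g = (
            const
            + np.tensordot(alpha - 1, lt, axes=1)
            - np.tensordot(beta - 1, lc, axes=1)
        )
    else:
        const = float((betaln(beta, alpha) - betaln(alpha, beta)).sum())
        g = const + np.tensordot(alpha - beta, lt - lc, axes=1)
    return g + math.log(rho / (1 - rho))


def run_lfm(
    thetas: list[ConfidenceMatrix], config: LFMConfig
) -> tuple[ConsensusPrior, MCMCTrace]:
    """Run the adaptive MCMC and return posterior edge frequencies as a prior.

    The chain starts from the empty network and alpha_k = beta_k = initial
    values (1 by default, i.e. every source initially carries no weight).
    Every ``param_move_period``-th iteration performs a joint log-scale
    Gaussian parameter move instead of a structure move; after every
    ``cov_update_period`` parameter moves the kernel covariance is refreshed
    from the empirical covariance of the accumulated log-parameter samples.
    The consensus prior is the mean of the post-burn-in network samples,
    clipped into [EPS, 1 - EPS].
    """
    thetas = [validate_confidence_matrix(t) for t in thetas]
    labels = check_same_labels(thetas)
    m = len(labels)
    if m < 2:
        raise ValueError("need at least 2 nodes")
    kk = len(thetas)
    rng = np.random.default_rng(config.rng_seed)
    form = config.likelihood_form
    rho = config.edge_prior_rho
    lo, hi = config.param_bounds
    llo, lhi = math.log(lo), math.log(hi)
    n_cells = m * (m - 1)

    clipped = np.stack([clip_prior(t.values) for t in thetas])
    off = ~np.eye(m, dtype=bool)
    lt = np.where(off, np.log(clipped, where=off[None], out=np.zeros_like(clipped)), 0.0)
    lc = np.where(off, np.log1p(-clipped, where=off[None], out=np.zeros_like(clipped)), 0.0)
    ltf = lt.reshape(kk, m * m)
    lcf = lc.reshape(kk, m * m)
    tot_t = lt.reshape(kk, -1).sum(axis=1)
    tot_c = lc.reshape(kk, -1).sum(axis=1)

    alpha = np.full(kk, float(config.init_alpha))
    beta = np.full(kk, float(config.init_beta))
    if not (lo <= config.init_alpha <= hi and lo <= config.init_beta <= hi):
        raise ValueError("initial parameters outside param_bounds")
    gain = _gain_matrix(alpha, beta, lt, lc, rho, form)

    adj = np.zeros((m, m), dtype=np.int8)
    edges: list[tuple[int, int]] = []
    epos: dict[tuple[int, int], int] = {}
    n_edges = 0
    n_rev = 0  # edges whose reverse is absent

    counts = np.zeros((m, m))
    last = np.zeros((m, m), dtype=np.int64)

    param_hist: list[np.ndarray] = []
    param_iters: list[int] = []
    lp_trace: list[float] = []
    lp_iters: list[int] = []
    prop = {"insert": 0, "delete": 0, "reverse": 0, "param": 0}
    acc = {"insert": 0, "delete": 0, "reverse": 0, "param": 0}

    chol = np.eye(2 * kk)
    n_param_moves = 0
    # acceptance-targeted global scale on top of the empirical covariance;
    # 2.38^2/d is the classical optimal-scaling start
    kernel_scale = 2.38**2 / (2 * kk)
    win_prop = win_acc = 0

    def present_stats() -> tuple[np.ndarray, np.ndarray]:
        if not edges:
            return np.zeros(kk), np.zeros(kk)
        idx = np.array([i * m + j for (i, j) in edges], dtype=np.intp)
        return ltf[:, idx].sum(axis=1), lcf[:, idx].sum(axis=1)

    def edge_prior_term() -> float:
        return n_edges * math.log(rho) + (n_cells - n_edges) * math.log(1 - rho)

    def add_edge(i: int, j: int, ts: int) -> None:
        nonlocal n_edges, n_rev
        adj[i, j] = 1
        epos[(i, j)] = len(edges)
        edges.append((i, j))
        n_edges += 1
        n_rev += 1 - 2 * int(adj[j, i])
        if ts >= 0:
            last[i, j] = ts

    def del_edge(i: int, j: int, ts: int) -> None:
        nonlocal n_edges, n_rev
        adj[i, j] = 0
        p = epos.pop((i, j))
        tail = edges.pop()
        if p < len(edges):
            edges[p] = tail
            epos[tail] = p
        n_edges -= 1
        n_rev += 2 * int(adj[j, i]) - 1
        if ts >= 0:
            counts[i, j] += ts - last[i, j]

    total_iters = config.burn_in + config.samples
    log = math.log
    exp = math.exp
    rand = rng.random
    randint = rng.integers

    for t in range(total_iters):
        ts = t - config.burn_in  # sampling-phase clock; negative during burn-in
        if not config.fix_params and (t + 1) % config.param_move_period == 0:
            prop["param"] += 1
            win_prop += 1
            sp_t, sp_c = present_stats()
            cur = _stats_loglik(
                alpha, beta, n_edges, n_cells, sp_t, sp_c, tot_t, tot_c, form
            )
            z = np.concatenate([np.log(alpha), np.log(beta)])
            zp = z + chol @ rng.standard_normal(2 * kk)
            if (zp >= llo).all() and (zp <= lhi).all():
                ap, bp = np.exp(zp[:kk]), np.exp(zp[kk:])
                new = _stats_loglik(
                    ap, bp, n_edges, n_cells, sp_t, sp_c, tot_t, tot_c, form
                )
                d = new - cur
                if d >= 0 or rand() < exp(d):
                    alpha, beta = ap, bp
                    z = zp
                    cur = new
                    gain = _gain_matrix(alpha, beta, lt, lc, rho, form)
                    acc["param"] += 1
                    win_acc += 1
            param_hist.append(z)
            param_iters.append(t)
            n_param_moves += 1
            if n_param_moves % config.cov_update_period == 0 and len(param_hist) >= 20:
                # retune the overall step size toward ~23% acceptance, then
                # refresh the covariance from the recent half of the samples
                # (the early free-wandering phase would otherwise inflate it)
                rate = win_acc / win_prop
                kernel_scale = float(
                    np.clip(kernel_scale * exp(2.0 * (rate - 0.234)), 1e-6, 10.0)
                )
                win_prop = win_acc = 0
                recent = np.asarray(param_hist[len(param_hist) // 2:])
                cov = np.cov(recent.T) * kernel_scale + 1e-6 * np.eye(2 * kk)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    chol = np.eye(2 * kk)
            if config.trace_every and t % config.trace_every == 0:
                lp_trace.append(cur + edge_prior_term())
                lp_iters.append(t)
            continue

        n_moves = n_cells + n_rev
        u = rand() * n_moves
        if u < n_cells - n_edges:
            kind = "insert"
            while True:
                i = int(randint(m))
                j = int(randint(m))
                if i != j and adj[i, j] == 0:
                    break
            delta = gain[i, j]
            d_rev = 1 - 2 * int(adj[j, i])
        elif u < n_cells:
            kind = "delete"
            i, j = edges[int(randint(n_edges))]
            delta = -gain[i, j]
            d_rev = 2 * int(adj[j, i]) - 1
        else:
            kind = "reverse"
            while True:
                i, j = edges[int(randint(n_edges))]
                if adj[j, i] == 0:
                    break
            delta = gain[j, i] - gain[i, j]
            d_rev = 0
        prop[kind] += 1
        log_acc = delta + log(n_moves) - log(n_moves + d_rev)
        if log_acc >= 0 or rand() < exp(log_acc):
            acc[kind] += 1
            if kind == "insert":
                add_edge(i, j, ts)
            elif kind == "delete":
                del_edge(i, j, ts)
            else:
                del_edge(i, j, ts)
                add_edge(j, i, ts)
        if config.trace_every and t % config.trace_every == 0:
            sp_t, sp_c = present_stats()
            lp_trace.append(
                _stats_loglik(alpha, beta, n_edges, n_cells, sp_t, sp_c, tot_t, tot_c, form)
                + edge_prior_term()
            )
            lp_iters.append(t)

    # close open on-intervals at the end of the sampling phase
    for (i, j) in edges:
        counts[i, j] += config.samples - last[i, j]
    freq = counts / config.samples
    np.fill_diagonal(freq, 0.0)

    rates = {k: (acc[k] / prop[k] if prop[k] else math.nan) for k in prop}
    trace = MCMCTrace(
        edge_frequency=freq,
        param_samples=np.asarray(param_hist) if param_hist else np.empty((0, 2 * kk)),
        param_sample_iters=np.asarray(param_iters, dtype=np.int64),
        acceptance_rates=rates,
        log_posterior_trace=np.asarray(lp_trace),
        log_posterior_iters=np.asarray(lp_iters, dtype=np.int64),
        burn_in=config.burn_in,
    )
    prior = ConsensusPrior(labels, clip_prior(freq), PriorMethod.LFM)
    return prior, trace


def exact_posterior_enumeration(
    thetas: list[ConfidenceMatrix],
    params: BetaSourceParams,
    config: LFMConfig,
) -> np.ndarray:
    """Exact posterior edge probabilities by summing over every digraph.

    Enumerates all 2^(m(m-1)) directed graphs (m <= 4) and normalises the
    exponentiated log posterior at fixed Beta parameters; serves as the
    ground-truth oracle for the MCMC edge frequencies.
    """
    thetas = [validate_confidence_matrix(t) for t in thetas]
    labels = check_same_labels(thetas)
    m = len(labels)
    if m > 4:
        raise ValueError("exact enumeration limited to m <= 4")
    cells = [(i, j) for i in range(m) for j in range(m) if i != j]
    n_c = len(cells)
    logps = np.empty(2**n_c)
    membership = np.zeros((2**n_c, n_c), dtype=bool)
    for mask in range(2**n_c):
        adj = np.zeros((m, m), dtype=np.int8)
        for b, (i, j) in enumerate(cells):
            if mask >> b & 1:
                adj[i, j] = 1
                membership[mask, b] = True
        omega = DirectedNetwork(labels, adj)
        logps[mask] = log_posterior(omega, thetas, params, config)
    log_z = logsumexp(logps)
    probs = np.zeros((m, m))
    for b, (i, j) in enumerate(cells):
        sel = membership[:, b]
        probs[i, j] = math.exp(logsumexp(logps[sel]) - log_z)
    return probs
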