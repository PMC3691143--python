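"""Closed-form consensus priors: Noisy-OR, rank variants, and baselines.

Given K edge-confidence matrices Theta_1..Theta_K over the same node set, each
combiner produces a single consensus prior matrix B:

* Noisy-OR (NOM):      B_ij = 1 - prod_k (1 - theta^k_ij) — one strong source
  suffices to make an edge believable.
* Independent product (IP):  B_ij = prod_k theta^k_ij — treats sources as
  statistically independent; many sources drive entries toward 0.
* Mean prior (MP):     B_ij = mean_k theta^k_ij.

Each combiner has a rank variant (NOM.RNK, IP.RNK, MP.RNK) that first replaces
every source's raw confidences by within-source relative ranks (average rank of
the cell divided by the maximum rank), making the combination invariant to
monotone rescalings of individual sources.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .core import (
    ConfidenceMatrix,
    ConsensusPrior,
    PriorMethod,
    check_same_labels,
    clip_prior,
    validate_confidence_matrix,
)


class RankMatrix(ConfidenceMatrix):
    """A confidence matrix whose entries are within-source relative ranks in (0, 1]."""


def rank_transform(
    matrix: ConfidenceMatrix, direction: str = "confidence_monotone"
) -> RankMatrix:
    """Replace off-diagonal confidences by relative ranks.

    Cells are ranked jointly over all m(m-1) off-diagonal positions, ties
    receiving the average rank, and every rank is divided by the maximum rank
    so the top cell(s) map to exactly 1.

    Parameters
    ----------
    direction:
        ``"confidence_monotone"`` (default): the largest confidence receives
        the largest relative rank (1), so high values keep meaning high
        support. ``"paper_descending"``: ranks are assigned in descending
        order of confidence (best cell gets rank 1) before division, the
        literal reading of rank assignment "in descending order".
    """
    matrix = validate_confidence_matrix(matrix)
    m = matrix.m
    off = ~np.eye(m, dtype=bool)
    vals = matrix.values[off]
    if direction == "confidence_monotone":
        ranks = rankdata(vals, method="average")
    elif direction == "paper_descending":
        ranks = rankdata(-vals, method="average")
    else:
        raise ValueError(f"unknown rank direction: {direction}")
    rel = ranks / ranks.max()
    out = np.zeros((m, m))
    out[off] = rel
    return RankMatrix(matrix.node_labels, out, matrix.source_name)


def _combined(thetas, reducer, method: PriorMethod, clip: bool) -> ConsensusPrior:
    thetas = [validate_confidence_matrix(t) for t in thetas]
    labels = check_same_labels(thetas)
    stack = np.stack([t.values for t in thetas])
    vals = reducer(stack)
    np.fill_diagonal(vals, 0.0)
    if clip:
        vals = clip_prior(vals)
    return ConsensusPrior(labels, vals, method)


def noisy_or(thetas, clip: bool = True) -> ConsensusPrior:
    """Noisy-OR combination: ``B_ij = 1 - prod_k (1 - theta^k_ij)``.

    With ``clip=True`` (default) the result is clipped into
    ``[EPS, 1 - EPS]`` so it can be used directly in log-scale structure
    scores; ``clip=False`` keeps the exact arithmetic (with all-{0,1} inputs
    the result is then exactly the logical OR of the sources).
    """
    return _combined(
        thetas, lambda s: 1.0 - np.prod(1.0 - s, axis=0), PriorMethod.NOM, clip
    )


def noisy_or_rnk(
    thetas, clip: bool = True, direction: str = "confidence_monotone"
) -> ConsensusPrior:
    """Noisy-OR on within-source relative ranks (NOM.RNK)."""
    ranked = [rank_transform(t, direction) for t in thetas]
    prior = noisy_or(ranked, clip=clip)
    return ConsensusPrior(prior.node_labels, prior.values, PriorMethod.NOM_RNK)


def independent_product(thetas, clip: bool = True) -> ConsensusPrior:
    """Independence prior: ``B_ij = prod_k theta^k_ij``."""
    return _combined(thetas, lambda s: np.prod(s, axis=0), PriorMethod.IP, clip)


def independent_product_rnk(
    thetas, clip: bool = True, direction: str = "confidence_monotone"
) -> ConsensusPrior:
    """Independence prior on within-source relative ranks (IP.RNK)."""
    ranked = [rank_transform(t, direction) for t in thetas]
    prior = independent_product(ranked, clip=clip)
    return ConsensusPrior(prior.node_labels, prior.values, PriorMethod.IP_RNK)


def mean_prior(thetas, clip: bool = True) -> ConsensusPrior:
    """Unweighted average prior: ``B_ij = (1/K) sum_k theta^k_ij``."""
    return _combined(thetas, lambda s: s.mean(axis=0), PriorMethod.MP, clip)


def mean_prior_rnk(
    thetas, clip: bool = True, direction: str = "confidence_monotone"
) -> ConsensusPrior:
    """Average of within-source relative ranks (MP.RNK, the Marbach-style combiner)."""
    ranked = [rank_transform(t, direction) for t in thetas]
    prior = mean_prior(ranked, clip=clip)
    return ConsensusPrior(prior.node_labels, prior.values, PriorMethod.MP_RNK)


#: Combiners addressable by method name (LFM lives in :mod:`netprior.lfm`).
COMBINERS = {
    "NOM": noisy_or,
    "NOM.RNK": noisy_or_rnk,
    "IP": independent_product,
    "IP.RNK": independent_product_rnk,
    "MP": mean_prior,
    "MP.RNK": mean_prior_rnk,
}


def combine(method: str, thetas, **kwargs) -> ConsensusPrior:
    """Dispatch a closed-form combiner by its method name."""
    try:
        fn = COMBINERS[method]
    except KeyError:
        raise ValueError(
            f"unknown combination method {method!r}; choose from {sorted(COMBINERS)}"
        ) from None
    return fn(thetas, **kwargs)
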