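"""Threshold-sweep evaluation of edge priors and learned networks.

The central summary is the *optimal balanced accuracy* (oBAC): sweeping a
cutoff over the prior's edge confidences, an edge is predicted present when
its value reaches the cutoff; sensitivity and specificity against the
ground-truth adjacency are averaged into the balanced accuracy, and oBAC is
the maximum over all cutoffs.  A constant (uninformative) prior therefore
scores exactly 0.5.  Path-based metrics compare a learned network to a
reference network of (possibly indirect) interactions, and a paired Wilcoxon
signed-rank procedure with Benjamini–Hochberg correction compares methods
across replicate ground-truth networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binomtest, false_discovery_control, wilcoxon

from .core import DirectedNetwork


@dataclass
class EvaluationCurve:
    """Sensitivity/specificity sweep with its optimal-balanced-accuracy summary."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    bac: np.ndarray
    obac: float
    obac_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "bac": self.bac,
            }
        )


def _off_diag_vectors(values, truth: DirectedNetwork, ignore_direction: bool):
    values = np.asarray(values, dtype=float)
    m = truth.m
    if values.shape != (m, m):
        raise ValueError("value matrix shape does not match truth network")
    if ignore_direction:
        # collapse ordered pairs with OR semantics for truth, max for scores
        iu = np.triu_indices(m, k=1)
        v = np.maximum(values, values.T)[iu]
        t = (truth.adjacency | truth.adjacency.T)[iu].astype(bool)
    else:
        off = ~np.eye(m, dtype=bool)
        v = values[off]
        t = truth.adjacency[off].astype(bool)
    return v, t


def confusion_at_cutoff(
    prior_values,
    truth: DirectedNetwork,
    cutoff: float,
    ignore_direction: bool = False,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts with an edge predicted when value >= cutoff."""
    v, t = _off_diag_vectors(prior_values, truth, ignore_direction)
    pred = v >= cutoff
    tp = int((pred & t).sum())
    fp = int((pred & ~t).sum())
    tn = int((~pred & ~t).sum())
    fn = int((~pred & t).sum())
    return tp, fp, tn, fn


def evaluation_curve(
    prior_values,
    truth: DirectedNetwork,
    ignore_direction: bool = False,
) -> EvaluationCurve:
    """Sweep all distinct confidence values (plus endpoints) and summarise.

    The cutoff grid is the set of unique prior values together with 0 and a
    value just above 1, guaranteeing the all-positive and all-negative rows
    are present, so oBAC >= 0.5 always.
    """
    v, t = _off_diag_vectors(prior_values, truth, ignore_direction)
    pos = int(t.sum())
    neg = int((~t).sum())
    if pos == 0 or neg == 0:
        raise ValueError("truth network must have at least one edge and one non-edge")
    cutoffs = np.unique(np.concatenate([v, [0.0, np.nextafter(1.0, 2.0)]]))
    pred = v[None, :] >= cutoffs[:, None]
    tp = (pred & t).sum(axis=1)
    tn = (~pred & ~t).sum(axis=1)
    sens = tp / pos
    spec = tn / neg
    bac = 0.5 * (sens + spec)
    best = int(np.argmax(bac))
    return EvaluationCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        bac=bac,
        obac=float(bac[best]),
        obac_cutoff=float(cutoffs[best]),
    )


def obac(prior_values, truth: DirectedNetwork, ignore_direction: bool = False) -> float:
    """Optimal balanced accuracy of a confidence matrix against a truth network."""
    return evaluation_curve(prior_values, truth, ignore_direction).obac


def path_explained_fraction(
    inferred: DirectedNetwork, reference: DirectedNetwork, view: str
) -> float:
    """Fraction of edges/connectivity explained across two networks.

    ``view="model"``: fraction of inferred edges (u, v) for which the
    reference contains a directed path u -> v, i.e. how much of the learned
    model the reference knowledge can explain (possibly via intermediates).
    ``view="knowledge"``: fraction of ordered pairs that are path-connected
    in the reference and are also path-connected in the inferred network,
    i.e. how much of the known connectivity the model preserves.
    """
    if inferred.node_labels != reference.node_labels:
        raise ValueError("node label mismatch")
    ref = reference.to_networkx()
    inf = inferred.to_networkx()
    if view == "model":
        edges = inferred.edges()
        if not edges:
            raise ValueError("model view undefined for an empty inferred network")
        reach = {u: nx.descendants(ref, u) for u, _ in edges}
        hit = sum(1 for u, v in edges if v in reach[u])
        return hit / len(edges)
    if view == "knowledge":
        pairs = [
            (u, v)
            for u in reference.node_labels
            for v in nx.descendants(ref, u)
        ]
        if not pairs:
            raise ValueError("knowledge view undefined: reference has no connected pairs")
        inf_reach = {u: nx.descendants(inf, u) for u in inferred.node_labels}
        hit = sum(1 for u, v in pairs if v in inf_reach[u])
        return hit / len(pairs)
    raise ValueError(f"unknown view: {view}")


def paired_method_comparison(obac_by_method: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests with Benjamini–Hochberg adjustment.

    ``obac_by_method`` has one row per replicate (paired by ground-truth
    network) and one column per method.  Returns a symmetric matrix of
    BH-adjusted p-values; the diagonal and comparisons of identical score
    vectors are 1 by convention.
    """
    df = pd.DataFrame(obac_by_method)
    if df.isna().any().any():
        raise ValueError("replicate table must be complete (paired design)")
    if len(df) < 5:
        raise ValueError("need at least 5 paired replicates")
    methods = list(df.columns)
    pairs, raw = [], []
    for a, b in [(x, y) for i, x in enumerate(methods) for y in methods[i + 1:]]:
        d = df[a].to_numpy() - df[b].to_numpy()
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(wilcoxon(df[a], df[b], zero_method="wilcox").pvalue)
        pairs.append((a, b))
        raw.append(p)
    adj = false_discovery_control(raw, method="bh") if raw else []
    out = pd.DataFrame(np.ones((len(methods), len(methods))), index=methods, columns=methods)
    for (a, b), p in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = p
    return out


def sign_test_greater(differences, alternative: str = "greater") -> float:
    """Exact sign test p-value that paired differences favour the first method.

    Ties (zero differences) are dropped, per the standard convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    return float(binomtest(int((d > 0).sum()), len(d), 0.5, alternative=alternative).pvalue)
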