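"""TSV-based file formats for matrices, networks and categorical datasets.

Matrices travel as tab-separated tables with a header row and a first column
of node labels; networks as two-column edge lists or SIF; datasets as
integer tables with variable labels in the header.  Every writer can embed a
provenance comment header (``#``-prefixed lines: tool version, seed, config
hash) which readers skip.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bn import CategoricalDataset
from .core import ConfidenceMatrix, ConsensusPrior, DirectedNetwork, PriorMethod

logger = logging.getLogger("netprior")

SIF_RELATION = "regulates"


def provenance_lines(seed=None, config_hash=None) -> list[str]:
    parts = [f"netprior {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return ["# " + " ".join(parts)]


def _write_with_header(path, body: str, seed=None, config_hash=None) -> None:
    text = "\n".join(provenance_lines(seed, config_hash)) + "\n" + body
    Path(path).write_text(text)


def write_matrix(
    path,
    matrix: ConfidenceMatrix | ConsensusPrior,
    seed=None,
    config_hash=None,
) -> None:
    """Write a labeled matrix as TSV (12 significant digits)."""
    df = pd.DataFrame(
        matrix.values, index=matrix.node_labels, columns=matrix.node_labels
    )
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", float_format="%.12g")
    _write_with_header(path, buf.getvalue(), seed, config_hash)


def read_matrix(path, labels=None, as_prior: str | None = None):
    """Read a labeled TSV matrix back as a ConfidenceMatrix or ConsensusPrior.

    ``labels``, when given, reorders rows and columns into that label order
    (the matrix is permuted consistently).  ``as_prior`` names the combiner
    method and switches the return type to ConsensusPrior.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse matrix TSV: {exc}") from exc
    if df.isna().any().any():
        i = int(np.argmax(df.isna().any(axis=1).to_numpy()))
        j = int(np.argmax(df.isna().iloc[i].to_numpy()))
        raise ValueError(
            f"{path}: missing cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels do not match column labels")
    if labels is not None:
        missing = set(labels) - set(df.index)
        if missing:
            raise ValueError(f"{path}: requested labels not present: {sorted(missing)}")
        df = df.loc[list(labels), list(labels)]
    vals = df.to_numpy(dtype=float)
    node_labels = tuple(str(x) for x in df.index)
    if as_prior:
        return ConsensusPrior(node_labels, vals, PriorMethod(as_prior))
    return ConfidenceMatrix(node_labels, vals, source_name=path.stem)


def write_network(
    path,
    net: DirectedNetwork,
    format: str = "edgelist",
    seed=None,
    config_hash=None,
    node_sidecar: bool = True,
) -> None:
    """Write a network as an edge list or SIF; isolated nodes go to a sidecar.

    The sidecar ``<path>.nodes`` lists every node label (one per line) so
    isolated nodes survive a round trip.
    """
    if format == "edgelist":
        rows = [f"{u}\t{v}" for u, v in net.edges()]
    elif format == "sif":
        rows = [f"{u}\t{SIF_RELATION}\t{v}" for u, v in net.edges()]
    else:
        raise ValueError(f"unknown network format: {format}")
    _write_with_header(path, "\n".join(rows) + ("\n" if rows else ""), seed, config_hash)
    if node_sidecar:
        Path(str(path) + ".nodes").write_text("\n".join(net.node_labels) + "\n")


def read_network(path, format: str = "edgelist") -> DirectedNetwork:
    """Read an edge-list or SIF network; self-loop rows are rejected."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen = set()
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if format == "edgelist":
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated labels")
            u, v = parts
        elif format == "sif":
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected source, relation, target")
            u, _, v = parts
        else:
            raise ValueError(f"unknown network format: {format}")
        if u == v:
            raise ValueError(f"{path}:{ln}: self-loop {u}->{v} rejected")
        if (u, v) in seen:
            logger.warning("%s:%d: duplicate edge %s->%s collapsed", path, ln, u, v)
            continue
        seen.add((u, v))
        edges.append((u, v))
    sidecar = Path(str(path) + ".nodes")
    if sidecar.exists():
        labels = [x for x in sidecar.read_text().splitlines() if x.strip()]
    else:
        labels = list(dict.fromkeys([u for e in edges for u in e]))
    return DirectedNetwork.from_edges(labels, edges)


def write_dataset(path, data: CategoricalDataset, seed=None, config_hash=None) -> None:
    df = pd.DataFrame(data.rows, columns=data.variable_labels)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    _write_with_header(path, buf.getvalue(), seed, config_hash)


def read_dataset(path, levels=None) -> CategoricalDataset:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    rows = df.to_numpy()
    if not np.issubdtype(rows.dtype, np.integer):
        raise ValueError(f"{path}: dataset cells must be integers")
    if levels is None:
        levels = [int(rows[:, j].max()) + 1 for j in range(rows.shape[1])]
    return CategoricalDataset(tuple(df.columns), levels, rows)
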