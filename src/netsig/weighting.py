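"""Convert the generic FI network into a disease-specific weighted graph.

Each functional-interaction edge gets the absolute Pearson correlation of
its two genes' expression profiles as weight; the signed correlation is kept
alongside as provenance (edge attribute ``pcc``). A ``unit`` mode assigns
weight 1 to every retained edge, which reduces downstream clustering to the
unweighted, tissue-agnostic network for comparison.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .io import ExpressionDataset

__all__ = ["pearson_cc", "weight_network"]

log = logging.getLogger(__name__)


def pearson_cc(x, y) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Requires length >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def weight_network(net: nx.Graph, expr: ExpressionDataset,
                   mode: str = "pcc") -> nx.Graph:
    """Weight FI edges by expression correlation.

    The output network is restricted to edges whose both genes are measured
    in ``expr``. In ``"pcc"`` mode each edge carries ``weight = |PCC|`` and
    ``pcc`` = signed PCC; in ``"unit"`` mode every retained edge has weight
    1.0. Edges with an undefined correlation (a constant gene) are dropped
    and logged.
    """
    if mode not in ("pcc", "unit"):
        raise ValueError(f"mode must be 'pcc' or 'unit', got {mode!r}")
    gene_idx = expr.gene_index()
    shared = [g for g in net.nodes if g in gene_idx]
    if not shared:
        raise ValueError("no genes shared between network and expression dataset")

    out = nx.Graph()
    out.add_nodes_from(shared)

    if mode == "unit":
        for a, b in net.edges:
            if a in gene_idx and b in gene_idx:
                out.add_edge(a, b, weight=1.0, pcc=1.0)
        return out

    # standardize rows once so each edge PCC is a dot product
    mat = expr.values
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    nz = sd[:, 0] > 0
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n = expr.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to weight edges")

    dropped = 0
    for a, b in net.edges:
        ia = gene_idx.get(a)
        ib = gene_idx.get(b)
        if ia is None or ib is None:
            continue
        if not (nz[ia] and nz[ib]):
            dropped += 1
            continue
        pcc = float(np.clip(z[ia] @ z[ib] / (n - 1), -1.0, 1.0))
        out.add_edge(a, b, weight=abs(pcc), pcc=pcc)
    if dropped:
        log.warning("weight_network: dropped %d edge(s) with undefined PCC", dropped)
    return out
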