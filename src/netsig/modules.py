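"""Module filtering and the module-level expression matrix.

MCL produces many tiny clusters; only modules of at least ``min_size`` genes
whose average intra-module |PCC| is at least ``min_avg_pcc`` are kept
(defaults 8 and 0.25, both thresholds inclusive). Each surviving module is
then summarized per sample by the mean expression of its member genes,
giving a modules x samples matrix that feeds the supervised PCA survival
model.

The average PCC is taken over FI edges internal to the module, not over all
gene pairs: the per-edge |PCC| is exactly the quantity the weighted network
carries. An all-pairs mode is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .mcl import GeneModule, module_avg_weight_from_net

__all__ = ["ModuleFilterParams", "ModuleExpressionMatrix", "module_avg_weight",
           "filter_modules", "module_expression_matrix"]

log = logging.getLogger(__name__)


@dataclass
class ModuleFilterParams:
    min_size: int = 8
    min_avg_pcc: float = 0.25

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0 <= self.min_avg_pcc <= 1:
            raise ValueError("min_avg_pcc must be in [0, 1]")


def module_avg_weight(module: GeneModule, net: nx.Graph,
                      all_pairs: bool = False, expr: ExpressionDataset | None = None) -> float:
    """Average |PCC| of a module, over intra-module FI edges.

    NaN when the module has no internal edge (such a module fails the
    filter). ``all_pairs=True`` averages |PCC| over all gene pairs instead,
    which requires the expression dataset.
    """
    if not all_pairs:
        return module_avg_weight_from_net(module.genes, net)
    if expr is None:
        raise ValueError("all_pairs mode needs the expression dataset")
    idx = expr.gene_index()
    rows = [idx[g] for g in module.genes if g in idx]
    if len(rows) < 2:
        return float("nan")
    cc = np.corrcoef(expr.values[rows])
    iu = np.triu_indices(len(rows), k=1)
    return float(np.abs(cc[iu]).mean())


def filter_modules(modules: list[GeneModule], net: nx.Graph,
                   params: ModuleFilterParams | None = None) -> list[GeneModule]:
    """Keep modules with size >= min_size and avg |PCC| >= min_avg_pcc.

    Both thresholds are inclusive. Survivors are renumbered 1..k by
    decreasing size (ties by lexicographically smallest member).
    """
    params = params or ModuleFilterParams()
    kept = []
    for m in modules:
        avg = module_avg_weight(m, net)
        if m.size >= params.min_size and avg >= params.min_avg_pcc:
            kept.append(GeneModule(genes=list(m.genes), avg_weight=avg))
    kept.sort(key=lambda m: (-m.size, m.genes[0]))
    for rank, m in enumerate(kept, start=1):
        m.rank_id = rank
    return kept


@dataclass
class ModuleExpressionMatrix:
    """Modules x samples matrix of mean member-gene expression."""

    modules: list[GeneModule]
    samples: list[str]
    values: np.ndarray
    coverage: np.ndarray  # per-module fraction of member genes measured

    @property
    def feature_ids(self) -> list[str]:
        return [f"M{m.rank_id}" for m in self.modules]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.samples)


def module_expression_matrix(modules: list[GeneModule], expr: ExpressionDataset,
                             on_empty: str = "error") -> ModuleExpressionMatrix:
    """Mean member-gene expression per module across samples.

    Genes absent from the dataset are excluded from the mean (coverage is
    recorded and a warning logged). A module with zero measured genes raises
    by default; ``on_empty="drop"`` excludes it with a warning instead.
    """
    idx = expr.gene_index()
    rows, cov, kept = [], [], []
    for m in modules:
        present = [idx[g] for g in m.genes if g in idx]
        if not present:
            if on_empty == "drop":
                log.warning("module %d has no measured genes; dropped", m.rank_id)
                continue
            raise ValueError(f"module {m.rank_id} has no genes measured in {expr.name}")
        if len(present) < m.size:
            log.warning("module %d: %d/%d genes measured in %s",
                        m.rank_id, len(present), m.size, expr.name)
        rows.append(expr.values[present].mean(axis=0))
        cov.append(len(present) / m.size)
        kept.append(m)
    return ModuleExpressionMatrix(
        modules=kept,
        samples=list(expr.samples),
        values=np.asarray(rows, dtype=float),
        coverage=np.asarray(cov, dtype=float),
    )


def save_modules_tsv(modules: list[GeneModule], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank_id\tsize\tavg_weight\tgenes\n")
        for m in modules:
            fh.write(f"{m.rank_id}\t{m.size}\t{float(m.avg_weight)!r}\t{','.join(m.genes)}\n")


def modules_to_gene_sets(modules: list[GeneModule]) -> dict[str, set[str]]:
    return {f"MODULE_{m.rank_id}": set(m.genes) for m in modules}
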