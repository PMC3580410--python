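"""Supervised greedy subnetwork search (Chuang-style baseline).

For each seed gene the module grows one gene at a time: every candidate
within ``search_depth`` edges of the current module and within ``max_depth``
edges of the seed is scored, and the best one is added as long as it
improves the module score by more than ``min_improvement``. The module score
is -log10 of the Cox Wald P of the module's per-sample mean expression —
the same module-scoring rule used by the main pipeline. Resulting modules
are deduplicated by gene-set identity (keeping the highest-scoring
trajectory) and ranked by score.

This search is supervised — the survival outcome drives every growth step —
which is exactly the overtraining hazard the unsupervised MCL route avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExpressionDataset
from .mcl import GeneModule, module_avg_weight_from_net
from .survival import cox_fit

__all__ = ["GreedyParams", "greedy_search"]


@dataclass
class GreedyParams:
    search_depth: int = 1
    max_depth: int = 2
    min_improvement: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.search_depth <= self.max_depth:
            raise ValueError("need 1 <= search_depth <= max_depth")


def _module_score(rows: list[int], expr: ExpressionDataset, time, event) -> float:
    """-log10 Cox Wald P of the mean expression of the module's genes."""
    score = expr.values[rows].mean(axis=0)
    fit = cox_fit(score, time, event)
    return float(-np.log10(max(fit.wald_p[0], np.finfo(float).tiny)))


def greedy_search(net: nx.Graph, expr: ExpressionDataset, time=None, event=None,
                  params: GreedyParams | None = None,
                  seed_genes=None) -> list[GeneModule]:
    """Greedy survival-scored subnetwork search from every seed gene.

    Returns modules deduplicated by gene set and ranked by decreasing score
    (stored on ``GeneModule.score``). Every returned module is connected in
    the network and no member lies more than ``max_depth`` edges from its
    seed. Candidates whose Cox fit degenerates are skipped.
    """
    params = params or GreedyParams()
    time = expr.time if time is None else np.asarray(time, dtype=float)
    event = expr.event if event is None else np.asarray(event, dtype=int)
    if time is None or event is None:
        raise ValueError("survival annotations required")
    idx = expr.gene_index()
    measured = [g for g in sorted(net.nodes) if g in idx]
    if not measured:
        raise ValueError("no genes shared between network and expression dataset")
    if seed_genes is None:
        seed_genes = measured
    best: dict[frozenset, tuple[float, list[str]]] = {}

    for seed in seed_genes:
        if seed not in idx or seed not in net:
            continue
        reachable = nx.single_source_shortest_path_length(net, seed,
                                                          cutoff=params.max_depth)
        allowed = {g for g in reachable if g in idx}
        module = {seed}
        try:
            score = _module_score([idx[seed]], expr, time, event)
        except (ValueError, np.linalg.LinAlgError):
            continue
        while True:
            frontier: set[str] = set()
            layer = set(module)
            for _ in range(params.search_depth):
                nxt = {nb for g in layer for nb in net.neighbors(g)}
                frontier |= nxt
                layer = nxt
            candidates = (frontier & allowed) - module
            best_gene, best_score = None, -np.inf
            for cand in sorted(candidates):
                rows = [idx[g] for g in module | {cand}]
                try:
                    s = _module_score(rows, expr, time, event)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if s > best_score:
                    best_gene, best_score = cand, s
            if best_gene is None or best_score - score <= params.min_improvement:
                break
            module.add(best_gene)
            score = best_score
        key = frozenset(module)
        if key not in best or score > best[key][0]:
            best[key] = (score, sorted(module))

    modules = [
        GeneModule(genes=genes, score=s,
                   avg_weight=module_avg_weight_from_net(genes, net))
        for s, genes in best.values()
    ]
    modules.sort(key=lambda m: (-(m.score or 0.0), m.genes[0]))
    for rank, m in enumerate(modules, start=1):
        m.rank_id = rank
    return modules
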