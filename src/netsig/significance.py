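"""Permutation nulls, empirical P-values, overlap tests and the cross-dataset
P-value score.

The module-discovery null randomly reassigns gene-row labels over the same
expression matrix ("row-label" mode): every row keeps its values and its
relation to survival, but the gene <-> network correspondence is destroyed,
which is exactly the structure the discovered modules exploit. A within-row
sample-shuffle mode (destroying the expression/survival relation instead) is
available behind a flag. A second null draws random gene sets of a given
size from the measured FI-network genes and scores their mean expression
against survival.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionDataset
from .survival import cox_fit

__all__ = ["NullDistribution", "permute_expression", "random_gene_set_null",
           "empirical_pvalue", "hypergeometric_overlap", "pvalue_score",
           "bonferroni"]


@dataclass
class NullDistribution:
    statistic_name: str
    values: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_permutations:
            raise ValueError("values length must equal n_permutations")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.statistic_name}\n")
            for v in self.values:
                fh.write(f"{float(v)!r}\n")
        with open(str(path) + ".json", "w") as fh:
            json.dump({"statistic": self.statistic_name,
                       "n_permutations": self.n_permutations,
                       "seed": self.seed}, fh)


def permute_expression(expr: ExpressionDataset, seed: int,
                       mode: str = "row_label") -> ExpressionDataset:
    """Permutation null for module discovery.

    ``row_label`` (default): gene-row labels are randomly reassigned over
    the same matrix rows — the multiset of rows and all survival columns are
    unchanged, but gene identity (hence network position) is scrambled.
    ``within_row``: each row's values are shuffled independently across
    samples, destroying both co-expression and survival association.
    """
    rng = np.random.default_rng(seed)
    if mode == "row_label":
        perm = rng.permutation(expr.n_genes)
        values = expr.values[perm]
    elif mode == "within_row":
        values = np.stack([rng.permutation(row) for row in expr.values])
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    return ExpressionDataset(
        genes=list(expr.genes),
        samples=list(expr.samples),
        values=values,
        time=None if expr.time is None else expr.time.copy(),
        event=None if expr.event is None else expr.event.copy(),
        covariates=None if expr.covariates is None else expr.covariates.copy(),
        name=f"{expr.name}|perm",
        endpoint=expr.endpoint,
    )


def random_gene_set_null(net: nx.Graph, size: int, expr: ExpressionDataset,
                         time, event, n_trials: int, seed: int) -> NullDistribution:
    """Cox Wald P of mean expression of random size-matched network gene sets.

    Each trial draws ``size`` distinct genes uniformly from the network
    nodes measured in ``expr``, scores samples by their mean expression, and
    records the univariate Cox Wald P.
    """
    rng = np.random.default_rng(seed)
    idx = expr.gene_index()
    pool = sorted(g for g in net.nodes if g in idx)
    if size > len(pool):
        raise ValueError(f"size {size} exceeds the {len(pool)} measured network genes")
    rows = np.asarray([idx[g] for g in pool])
    pvals = np.empty(n_trials)
    for t in range(n_trials):
        pick = rng.choice(rows, size=size, replace=False)
        score = expr.values[pick].mean(axis=0)
        fit = cox_fit(score, time, event)
        pvals[t] = fit.wald_p[0]
    return NullDistribution(statistic_name="cox_wald_p_random_gene_set",
                            values=pvals, n_permutations=n_trials, seed=seed)


def empirical_pvalue(observed: float, null: NullDistribution,
                     direction: str = "less") -> float:
    """Add-one empirical P-value (r + 1)/(n + 1).

    ``direction="less"`` counts null values <= observed as at least as
    extreme (appropriate when the statistic is itself a P-value);
    ``"greater"`` counts null values >= observed.
    """
    if null.n_permutations < 1:
        raise ValueError("need at least one permutation")
    if direction == "less":
        r = int((null.values <= observed).sum())
    elif direction == "greater":
        r = int((null.values >= observed).sum())
    else:
        raise ValueError("direction must be 'less' or 'greater'")
    return (r + 1) / (null.n_permutations + 1)


def hypergeometric_overlap(setA, setB, background) -> float:
    """Upper-tail hypergeometric P of the overlap |A ∩ B|.

    P(X >= k) with population N = |background|, K = |B| successes, n = |A|
    draws, k = |A ∩ B|. Both sets must be contained in the background.
    """
    A, B, bg = set(setA), set(setB), set(background)
    if not A <= bg or not B <= bg:
        raise ValueError("sets must be contained in the background")
    k = len(A & B)
    return float(stats.hypergeom.sf(k - 1, len(bg), len(B), len(A)))


def pvalue_score(pvalues, base: float = 10.0) -> float:
    """Negative log of the geometric mean of P-values (default base 10).

    Equals the mean of -log10(p); higher is better. All P-values must be in
    (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must be in (0, 1]")
    return float(np.mean(-np.log(p) / np.log(base)))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted P-value: min(1, m * p)."""
    if not 0 < p <= 1 or m < 1:
        raise ValueError("need p in (0,1] and m >= 1")
    return min(1.0, m * p)
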