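"""End-to-end signature discovery and validation.

``NetworkSignatureModel`` wires the stages together: weight the FI network
by expression correlation, Markov-cluster it into modules, filter by size
and average |PCC|, build the module-level expression matrix, and fit a
supervised-PC survival model (threshold chosen by cross-validation unless
given). ``fit`` returns a ``SignatureResults`` carrying the modules, the
fitted superpc model, the per-module univariate Cox table, and methods for
validating on independent cohorts and for permutation significance testing.

All randomness (CV folds, permutations) flows from a single seed, so two
runs with the same inputs produce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset, load_expression, load_fi_network
from .mcl import GeneModule, MCLParams, mcl_cluster
from .modules import (ModuleExpressionMatrix, ModuleFilterParams,
                      filter_modules, module_expression_matrix,
                      modules_to_gene_sets, save_modules_tsv)
from .significance import NullDistribution, empirical_pvalue, permute_expression
from .superpc import SuperPC, SuperPCResults
from .survival import cox_fit, kaplan_meier_logrank
from .weighting import weight_network

__all__ = ["NetworkSignatureModel", "SignatureResults",
           "permutation_module_null", "signature_pvalue_scores"]

log = logging.getLogger(__name__)


def _module_cox_table(M: ModuleExpressionMatrix, time, event,
                      dataset: str) -> pd.DataFrame:
    """Per-module univariate Cox results (module, size, coef, HR, P)."""
    rows = []
    for m, row in zip(M.modules, M.values):
        try:
            fit = cox_fit(row, time, event)
            rows.append({"dataset": dataset, "module": m.rank_id, "size": m.size,
                         "coef": fit.coef[0], "HR": fit.hr[0],
                         "CI95_low": fit.ci95[0, 0], "CI95_high": fit.ci95[0, 1],
                         "P": fit.wald_p[0]})
        except (ValueError, np.linalg.LinAlgError):
            rows.append({"dataset": dataset, "module": m.rank_id, "size": m.size,
                         "coef": np.nan, "HR": np.nan,
                         "CI95_low": np.nan, "CI95_high": np.nan, "P": np.nan})
    return pd.DataFrame(rows)


class NetworkSignatureModel:
    """Discovery model: FI network + expression cohort -> prognostic modules.

    Parameters
    ----------
    network : networkx.Graph
        The (unweighted) functional-interaction network.
    expression : ExpressionDataset
        Training cohort with survival annotations.
    mcl_params, filter_params : stage parameters (paper defaults).
    weight_mode : "pcc" (disease-specific weights) or "unit" (unweighted
        comparison mode).
    folds, n_components : supervised-PC settings.
    seed : drives CV fold assignment (and nothing else during fit).
    """

    def __init__(self, network: nx.Graph, expression: ExpressionDataset,
                 mcl_params: MCLParams | None = None,
                 filter_params: ModuleFilterParams | None = None,
                 weight_mode: str = "pcc", folds: int = 10,
                 n_components: int = 3, cv_components: int = 1, seed: int = 0):
        if expression.time is None or expression.event is None:
            raise ValueError("training dataset needs survival annotations")
        self.network = network
        self.expression = expression
        self.mcl_params = mcl_params or MCLParams()
        self.filter_params = filter_params or ModuleFilterParams()
        self.weight_mode = weight_mode
        self.folds = folds
        self.n_components = n_components
        self.cv_components = cv_components
        self.seed = seed

    @classmethod
    def from_files(cls, network_path, expression_path, clinical_path,
                   **kwargs) -> "NetworkSignatureModel":
        net = load_fi_network(network_path)
        expr = load_expression(expression_path, clinical_path)
        return cls(net, expr, **kwargs)

    # ------------------------------------------------------------------
    def cluster_modules(self, expression: ExpressionDataset | None = None):
        """Stages 1-3: weight, cluster, filter. Returns (weighted_net, modules)."""
        expr = expression or self.expression
        weighted = weight_network(self.network, expr, mode=self.weight_mode)
        raw = mcl_cluster(weighted, self.mcl_params)
        modules = filter_modules(raw, weighted, self.filter_params)
        return weighted, modules

    def fit(self, threshold: float | None = None) -> "SignatureResults":
        """Run the full discovery pipeline.

        When ``threshold`` is None it is chosen by stratified k-fold
        cross-validation of the held-out Cox likelihood-ratio statistic.
        """
        weighted, modules = self.cluster_modules()
        if not modules:
            raise ValueError("no modules passed filters")
        M = module_expression_matrix(modules, self.expression)
        spc = SuperPC(M, self.expression.time, self.expression.event)
        cv_table = None
        if threshold is None:
            threshold, cv_table = spc.select_threshold_cv(
                folds=self.folds, cv_components=self.cv_components,
                seed=self.seed)
        superpc_res = spc.fit(threshold, n_components=self.n_components)
        superpc_res.cv_table = cv_table
        cox_table = _module_cox_table(M, self.expression.time,
                                      self.expression.event,
                                      self.expression.name)
        return SignatureResults(model=self, weighted_network=weighted,
                                modules=modules, module_matrix=M,
                                superpc=superpc_res, threshold=threshold,
                                cv_table=cv_table, module_cox_table=cox_table)


@dataclass
class SignatureResults:
    """Discovery output: modules, superpc model and training report."""

    model: NetworkSignatureModel | None
    weighted_network: nx.Graph
    modules: list[GeneModule]
    module_matrix: ModuleExpressionMatrix
    superpc: SuperPCResults
    threshold: float
    cv_table: pd.DataFrame | None
    module_cox_table: pd.DataFrame

    @property
    def retained_modules(self) -> list[GeneModule]:
        ids = {int(f[1:]) for f in self.superpc.retained}
        return [m for m in self.modules if m.rank_id in ids]

    def signature_genes(self) -> set[str]:
        return set().union(*(m.genes for m in self.retained_modules))

    def summary(self) -> str:
        lines = [
            "Network module prognostic signature",
            f"  modules passing filters: {len(self.modules)} "
            f"(sizes {self.modules[-1].size}..{self.modules[0].size})",
            f"  CV threshold: {self.threshold:.4g}; retained modules: "
            f"{', '.join(self.superpc.retained)} "
            f"({len(self.signature_genes())} genes)",
            "",
            "Per-component Cox fits (training):",
            self.superpc.component_table().to_string(
                float_format=lambda v: f"{v:.4g}"),
            "",
            "Per-module univariate Cox (training):",
            self.module_cox_table.to_string(index=False,
                                            float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def module_matrix_for(self, dataset: ExpressionDataset,
                          retained_only: bool = False) -> ModuleExpressionMatrix:
        """Training module definitions applied to another cohort.

        Unmeasured member genes are dropped from the mean (coverage is
        recorded); zero-coverage modules are excluded with a warning.
        """
        mods = self.retained_modules if retained_only else self.modules
        return module_expression_matrix(mods, dataset, on_empty="drop")

    def validate(self, dataset: ExpressionDataset,
                 discrete_component: int | None = None) -> dict:
        """Score an independent cohort with the trained model.

        Returns a dict with the per-component Cox table, the per-module
        univariate Cox table, the continuous component scores and (when
        ``discrete_component`` is given) the discrete grouping with its
        Kaplan-Meier log-rank test.
        """
        if dataset.time is None or dataset.event is None:
            raise ValueError("validation dataset needs survival annotations")
        M = self.module_matrix_for(dataset)
        scores = self.superpc.predict_continuous(M)
        comp_rows = []
        for k in range(self.superpc.n_components):
            try:
                fit = cox_fit(scores.iloc[:, k].to_numpy(), dataset.time,
                              dataset.event)
                comp_rows.append({"dataset": dataset.name, "component": f"PC{k+1}",
                                  "HR": fit.hr[0], "CI95_low": fit.ci95[0, 0],
                                  "CI95_high": fit.ci95[0, 1], "P": fit.wald_p[0]})
            except (ValueError, np.linalg.LinAlgError):
                comp_rows.append({"dataset": dataset.name, "component": f"PC{k+1}",
                                  "HR": np.nan, "CI95_low": np.nan,
                                  "CI95_high": np.nan, "P": np.nan})
        report = {
            "dataset": dataset.name,
            "coverage": dict(zip(M.feature_ids, M.coverage)),
            "component_cox": pd.DataFrame(comp_rows),
            "module_cox": _module_cox_table(M, dataset.time, dataset.event,
                                            dataset.name),
            "continuous_scores": scores,
        }
        if discrete_component is not None:
            groups = self.superpc.predict_discrete(M, component=discrete_component)
            if groups.nunique() == 2:
                km = kaplan_meier_logrank(dataset.time, dataset.event,
                                          groups.to_numpy())
                report["discrete_groups"] = groups
                report["km"] = km
            else:
                warnings.warn("discrete prediction produced a single group; "
                              "KM/log-rank skipped")
        return report

    # ------------------------------------------------------------------
    def save(self, out_dir) -> None:
        """Write the signature bundle (modules, model, reports) as text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_modules_tsv(self.modules, out / "modules.tsv")
        from .io import save_gmt
        save_gmt(modules_to_gene_sets(self.modules), out / "modules.gmt")
        M = self.module_matrix
        M.to_frame().to_csv(out / "module_matrix.tsv", sep="\t")
        (out / "superpc_model.json").write_text(self.superpc.to_json())
        self.module_cox_table.to_csv(out / "module_cox.tsv", sep="\t", index=False)
        self.superpc.component_table().to_csv(out / "superpc_components.tsv",
                                              sep="\t")
        if self.cv_table is not None:
            self.cv_table.to_csv(out / "cv.tsv", sep="\t", index=False)
        meta = {
            "threshold": self.threshold,
            "retained": self.superpc.retained,
            "modules": [{"rank_id": m.rank_id, "size": m.size,
                         "avg_weight": m.avg_weight, "genes": m.genes}
                        for m in self.modules],
        }
        (out / "signature.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, out_dir) -> "SignatureResults":
        """Reload a saved bundle (enough to validate new cohorts)."""
        out = Path(out_dir)
        meta = json.loads((out / "signature.json").read_text())
        modules = [GeneModule(genes=m["genes"], avg_weight=m["avg_weight"],
                              rank_id=m["rank_id"])
                   for m in meta["modules"]]
        superpc = SuperPCResults.from_json((out / "superpc_model.json").read_text())
        mm = pd.read_csv(out / "module_matrix.tsv", sep="\t", index_col=0)
        M = ModuleExpressionMatrix(modules=modules,
                                   samples=[str(c) for c in mm.columns],
                                   values=mm.to_numpy(dtype=float),
                                   coverage=np.ones(len(modules)))
        cox = pd.read_csv(out / "module_cox.tsv", sep="\t")
        return cls(model=None, weighted_network=nx.Graph(), modules=modules,
                   module_matrix=M, superpc=superpc,
                   threshold=meta["threshold"], cv_table=None,
                   module_cox_table=cox)


# ---------------------------------------------------------------------------
# Permutation experiment


def permutation_module_null(model: NetworkSignatureModel, n_permutations: int,
                            seed: int, mode: str = "row_label") -> NullDistribution:
    """Full-pipeline permutation null of the best module P-value.

    Each permutation reassigns gene-row labels, re-weights the network,
    re-clusters, re-filters, and records the minimum univariate Cox Wald P
    over surviving modules (1.0 when none survive). Comparing an observed
    module P against this null asks: could a module this significant arise
    with gene identity scrambled?
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_seed = int(rng.integers(0, 2 ** 31 - 1))
        expr_b = permute_expression(model.expression, perm_seed, mode=mode)
        try:
            _, modules = model.cluster_modules(expression=expr_b)
            if not modules:
                values[b] = 1.0
                continue
            M = module_expression_matrix(modules, expr_b)
            table = _module_cox_table(M, expr_b.time, expr_b.event, "perm")
            p = table["P"].dropna()
            values[b] = float(p.min()) if len(p) else 1.0
        except (ValueError, np.linalg.LinAlgError):
            values[b] = 1.0
    return NullDistribution(statistic_name="min_module_cox_wald_p",
                            values=values, n_permutations=n_permutations,
                            seed=seed)


def module_empirical_pvalues(results: SignatureResults,
                             null: NullDistribution) -> pd.DataFrame:
    """Empirical P per training module against a permutation null."""
    rows = []
    for _, row in results.module_cox_table.iterrows():
        if np.isnan(row["P"]):
            continue
        rows.append({"module": int(row["module"]), "P": row["P"],
                     "empirical_P": empirical_pvalue(row["P"], null,
                                                     direction="less")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signature comparison (P-value score across cohorts)


def signature_pvalue_scores(gene_sets: dict[str, set[str]],
                            datasets: list[ExpressionDataset]) -> pd.DataFrame:
    """Cross-cohort P-value score per gene signature.

    Each signature is scored per cohort by the univariate Cox Wald P of its
    mean member-gene expression; the summary score is the negative log10 of
    the geometric mean of those P-values (higher = more robust). Signatures
    with no measured genes in some cohort get NaN.
    """
    from .significance import pvalue_score

    rows = []
    for name, genes in gene_sets.items():
        pvals, per_ds = [], {}
        for ds in datasets:
            idx = ds.gene_index()
            present = [idx[g] for g in genes if g in idx]
            if not present or ds.time is None:
                per_ds[ds.name] = np.nan
                continue
            score = ds.values[present].mean(axis=0)
            try:
                fit = cox_fit(score, ds.time, ds.event)
                p = float(fit.wald_p[0])
            except (ValueError, np.linalg.LinAlgError):
                p = np.nan
            per_ds[ds.name] = p
            if np.isfinite(p):
                pvals.append(p)
        rows.append({"signature": name, "n_genes": len(genes),
                     **per_ds,
                     "pvalue_score": pvalue_score(pvals) if pvals else np.nan})
    return pd.DataFrame(rows).sort_values("pvalue_score", ascending=False,
                                          ignore_index=True)
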