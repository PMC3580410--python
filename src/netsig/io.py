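"""Reading, writing and preprocessing of networks, expression matrices and
clinical tables.

File conventions
----------------
* Functional-interaction (FI) network: tab-delimited edge list, two or more
  columns (geneA, geneB, optional annotation), no header required. Weighted
  networks are written as four columns (geneA, geneB, weight, signed_pcc).
* Expression: TSV, first column gene symbol, header row of sample ids.
* Clinical: TSV with columns ``sample``, ``time``, ``event`` followed by
  optional covariate columns.
* Gene sets: GMT (name, description, genes...).

Gene symbols are matched case-sensitively after whitespace trimming. Missing
expression values are rejected at load time; imputation is upstream of this
package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "load_fi_network",
    "save_fi_network",
    "load_expression",
    "save_expression",
    "load_clinical",
    "save_clinical",
    "load_gmt",
    "save_gmt",
    "collapse_probes",
    "zscore_transform",
]


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with survival annotations.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols, one per matrix row.
    samples : list of str
        Sample identifiers, one per matrix column.
    values : ndarray, shape (n_genes, n_samples)
        Log-scale intensities or z-scores (unitless).
    time : ndarray or None
        Per-sample survival duration (> 0; months or years, consistent
        within a dataset).
    event : ndarray or None
        Per-sample indicator, 1 = death/event observed, 0 = censored.
    covariates : DataFrame or None
        Optional per-sample covariate columns (numeric or binary), indexed
        by sample id.
    name : str
        Label used in reports.
    endpoint : str
        Survival endpoint tag, e.g. ``"os"`` (overall survival) or
        ``"dfs"`` (disease-free). Cohorts with a non-``"os"`` endpoint are
        excluded from pooled analyses by default.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    name: str = "dataset"
    endpoint: str = "os"

    def __post_init__(self) -> None:
        self.genes = [str(g).strip() for g in self.genes]
        self.samples = [str(s).strip() for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = pd.Index(self.genes)
            dup = sorted(dup[dup.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dup[:10]}")
        if np.isnan(self.values).any():
            raise ValueError("missing expression values are not allowed")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (len(self.samples),):
                raise ValueError("time length does not match samples")
            if not np.all(self.time > 0):
                raise ValueError("all survival times must be > 0")
        if self.event is not None:
            self.event = np.asarray(self.event)
            if self.event.shape != (len(self.samples),):
                raise ValueError("event length does not match samples")
            if not np.isin(self.event, [0, 1]).all():
                raise ValueError("event indicator must be 0 or 1")
            self.event = self.event.astype(int)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index()[gene]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        idx = self.gene_index()
        keep = [g for g in genes if g in idx]
        rows = [idx[g] for g in keep]
        return ExpressionDataset(
            genes=keep,
            samples=list(self.samples),
            values=self.values[rows],
            time=None if self.time is None else self.time.copy(),
            event=None if self.event is None else self.event.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
            name=self.name,
            endpoint=self.endpoint,
        )


# ---------------------------------------------------------------------------
# FI network


def load_fi_network(path) -> nx.Graph:
    """Load an undirected FI network from a tab-delimited edge list.

    Duplicate pairs (in either order) collapse to a single edge; self-loop
    lines are skipped with a warning. A third numeric column, when present,
    is stored as the edge ``weight``.
    """
    net = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = [t.strip() for t in line.split("\t")]
            if len(tokens) == 1:  # tolerate space-separated files
                tokens = line.split()
            if len(tokens) < 2 or not tokens[0] or not tokens[1]:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            a, b = tokens[0], tokens[1]
            if a == b:
                warnings.warn(f"{path}: line {lineno}: self-loop {a!r} skipped")
                continue
            attrs = {}
            if len(tokens) >= 3:
                try:
                    attrs["weight"] = float(tokens[2])
                except ValueError:
                    pass  # annotation column, not a weight
            if len(tokens) >= 4:
                try:
                    attrs["pcc"] = float(tokens[3])
                except ValueError:
                    pass
            net.add_edge(a, b, **attrs)
    return net


def save_fi_network(net: nx.Graph, path) -> None:
    """Write a network as TSV; weighted edges get weight and signed-PCC columns."""
    with open(path, "w") as fh:
        for a, b, data in sorted(net.edges(data=True)):
            if "weight" in data:
                pcc = data.get("pcc", data["weight"])
                fh.write(f"{a}\t{b}\t{float(data['weight'])!r}\t{float(pcc)!r}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Expression and clinical tables


def load_expression(path, clinical_path=None, name: str | None = None,
                    endpoint: str = "os") -> ExpressionDataset:
    """Load a genes x samples TSV, optionally joined with a clinical table."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    ds = ExpressionDataset(
        genes=list(df.index),
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        name=name or str(path),
        endpoint=endpoint,
    )
    if clinical_path is not None:
        attach_clinical(ds, load_clinical(clinical_path))
    return ds


def save_expression(ds: ExpressionDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(ds.samples) + "\n")
        for g, row in zip(ds.genes, ds.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_clinical(path) -> pd.DataFrame:
    """Load a clinical TSV (sample, time, event, covariates...) indexed by sample."""
    clin = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample", "time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    clin["sample"] = clin["sample"].astype(str).str.strip()
    return clin.set_index("sample")


def save_clinical(ds: ExpressionDataset, path) -> None:
    if ds.time is None or ds.event is None:
        raise ValueError("dataset has no survival annotations")
    cols = {"sample": ds.samples, "time": ds.time, "event": ds.event}
    df = pd.DataFrame(cols)
    if ds.covariates is not None:
        for c in ds.covariates.columns:
            df[c] = ds.covariates.loc[ds.samples, c].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def attach_clinical(ds: ExpressionDataset, clin: pd.DataFrame) -> ExpressionDataset:
    """Align a clinical table to a dataset's samples (in place)."""
    missing = [s for s in ds.samples if s not in clin.index]
    if missing:
        raise ValueError(f"samples without clinical rows: {missing[:10]}")
    clin = clin.loc[ds.samples]
    ds.time = clin["time"].to_numpy(dtype=float)
    ds.event = clin["event"].to_numpy()
    extra = [c for c in clin.columns if c not in ("time", "event")]
    ds.covariates = clin[extra].copy() if extra else None
    ds.__post_init__()
    return ds


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def load_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name = tokens[0].strip()
            genes = {t.strip() for t in tokens[2:] if t.strip()}
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"{path}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def save_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing


def collapse_probes(probe_matrix: pd.DataFrame,
                    mapping: dict[str, set[str]]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes mapping to several genes are removed; probes with no mapped gene
    are dropped; multiple probes for one gene are averaged elementwise.
    """
    rows: dict[str, list[np.ndarray]] = {}
    for probe in probe_matrix.index:
        genes = mapping.get(probe, set())
        if len(genes) != 1:
            continue  # ambiguous or unmapped probe
        (gene,) = genes
        rows.setdefault(str(gene).strip(), []).append(
            probe_matrix.loc[probe].to_numpy(dtype=float)
        )
    if not rows:
        return pd.DataFrame(columns=probe_matrix.columns)
    data = {g: np.mean(v, axis=0) for g, v in rows.items()}
    out = pd.DataFrame.from_dict(data, orient="index", columns=probe_matrix.columns)
    return out.loc[sorted(out.index)]


def zscore_transform(values, ddof: int = 1):
    """Standardize each gene row to mean 0, sd 1 (sample sd by default).

    Constant rows cannot be standardized; they are excluded and returned in
    a drop log.

    Returns
    -------
    (standardized, dropped) : the transformed matrix (same container type as
    the input) and the list of dropped row labels/indices.
    """
    if isinstance(values, pd.DataFrame):
        mat = values.to_numpy(dtype=float)
        labels = list(values.index)
    else:
        mat = np.asarray(values, dtype=float)
        labels = list(range(mat.shape[0]))
    sd = mat.std(axis=1, ddof=ddof)
    keep = sd > 0
    dropped = [labels[i] for i in np.where(~keep)[0]]
    if dropped:
        warnings.warn(f"zscore_transform: dropped {len(dropped)} constant row(s)")
    mat = mat[keep]
    mat = (mat - mat.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(mat, index=[l for l, k in zip(labels, keep) if k],
                            columns=values.columns), dropped
    return mat, dropped
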