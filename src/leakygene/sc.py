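"""Single-cell detection statistics.

QC filtering, log-normalisation, variable-gene ranking and per-cluster
detection tables.  Embedding and clustering (PCA / graph clustering / UMAP)
are deliberately not reimplemented: cluster labels are an input, either
ground truth from the simulator or externally computed for real data.  The
analysis-bearing outputs here are the per-cluster detection percentages and
mean normalised expression used to judge whether a gene is expressed in a
cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ScDataset",
    "ClusterGeneStats",
    "qc_filter_cells",
    "log_normalize",
    "rank_variable_genes",
    "cluster_gene_stats",
    "select_clusters_by_markers",
]


@dataclass
class ScDataset:
    """Sparse genes x cells UMI count matrix with per-cell cluster labels."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for a {n_genes}-row matrix"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for a {n_cells}-column matrix"
            )
        if len(self.cluster_labels) != n_cells:
            raise ValueError("one cluster label per cell is required")
        if self.counts.nnz:
            if self.counts.data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts.data, np.round(self.counts.data)):
                    raise ValueError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "ScDataset":
        keep = np.asarray(keep)
        return ScDataset(
            counts=sp.csr_matrix(self.counts[:, keep]),
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.cell_ids[i] for i in keep],
            cluster_labels=[self.cluster_labels[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.cluster_labels[i] for i in keep],
            metadata=dict(self.metadata),
        )


@dataclass
class ClusterGeneStats:
    """Per (gene, cluster) detection statistics.

    ``table`` has one row per (gene, cluster) with columns ``pct_detected``
    (0-100), ``mean_norm_expr`` (mean over all cells in the cluster, zeros
    included), ``n_cells``, ``nd`` (True when the gene is undetected in the
    cluster) and ``missing`` (True when the gene is absent from the matrix).
    """

    table: pd.DataFrame

    def get(self, gene: str, cluster: str) -> pd.Series:
        mask = (self.table["gene"] == gene) & (self.table["cluster"] == cluster)
        rows = self.table[mask]
        if rows.empty:
            raise KeyError((gene, cluster))
        return rows.iloc[0]


def qc_filter_cells(ds: ScDataset, min_features: int) -> ScDataset:
    """Remove cells detecting fewer than ``min_features`` genes.

    Removal is strict "less than": a cell with exactly ``min_features``
    detected genes is retained.
    """
    if min_features < 0:
        raise ValueError("min_features must be non-negative")
    n_features = np.asarray((ds.counts > 0).sum(axis=0)).ravel()
    keep = n_features >= min_features
    if not keep.any():
        raise ValueError(
            f"all cells removed by the min_features={min_features} filter"
        )
    if keep.all():
        return ds
    return ds.subset_cells(keep)


def log_normalize(ds: ScDataset, scale_factor: float = 10_000.0) -> sp.csr_matrix:
    """Per-cell count scaling to ``scale_factor`` total, then ln(1 + x).

    Natural log is used (the convention of the normalisation method this
    follows).  Zero counts map to exactly 0, so sparsity is preserved.
    """
    totals = np.asarray(ds.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        zero_cells = [ds.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cell(s) with zero total count: {zero_cells}")
    norm = ds.counts.tocsc(copy=True).astype(float)
    norm.data *= scale_factor / np.repeat(totals, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    return norm.tocsr()


def rank_variable_genes(ds: ScDataset, n: int = 2000) -> list[str]:
    """Rank genes by variance standardised against a mean-variance trend.

    The expected log10 variance is modelled as a quadratic in log10 mean
    (fitted over genes with positive variance); each gene's counts are then
    standardised by the trend's predicted standard deviation, clipped at
    sqrt(n_cells), and the variance of the clipped standardised values is
    the ranking statistic.  The top ``n`` gene ids are returned, most
    variable first.
    """
    if n > ds.n_genes:
        raise ValueError(f"requested {n} genes from a {ds.n_genes}-gene matrix")
    counts = ds.counts.astype(float)
    n_cells = ds.n_cells
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = counts.multiply(counts)
    mean_sq = np.asarray(sq.mean(axis=1)).ravel()
    var = (mean_sq - mean**2) * n_cells / max(n_cells - 1, 1)

    usable = (mean > 0) & (var > 0)
    std_var = np.zeros(ds.n_genes)
    if usable.sum() >= 3:
        log_mean = np.log10(mean[usable])
        log_var = np.log10(var[usable])
        coeffs = np.polyfit(log_mean, log_var, deg=min(2, usable.sum() - 1))
        expected_sd = np.sqrt(10 ** np.polyval(coeffs, np.log10(mean[usable])))
        clip = np.sqrt(n_cells)
        dense = np.asarray(counts[usable].todense())
        z = (dense - mean[usable][:, None]) / expected_sd[:, None]
        z = np.clip(z, -clip, clip)
        std_var[usable] = z.var(axis=1, ddof=1)
    elif usable.any():
        std_var[usable] = var[usable]

    order = np.argsort(-std_var, kind="stable")
    return [ds.gene_ids[i] for i in order[:n]]


def cluster_gene_stats(
    ds: ScDataset,
    normalised: sp.csr_matrix,
    genes: list[str],
) -> ClusterGeneStats:
    """Detection percentage and mean normalised expression per (gene, cluster).

    The mean averages over every cell in the cluster, zeros included.
    Genes absent from the matrix are reported with pct 0 and an explicit
    ``missing`` flag rather than raising.
    """
    labels = np.asarray(ds.cluster_labels)
    clusters = sorted(set(ds.cluster_labels))
    gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
    counts = ds.counts

    rows = []
    for gene in genes:
        idx = gene_index.get(gene)
        for cluster in clusters:
            cell_mask = labels == cluster
            n_cells = int(cell_mask.sum())
            if idx is None:
                rows.append(
                    {
                        "gene": gene,
                        "cluster": cluster,
                        "pct_detected": 0.0,
                        "mean_norm_expr": 0.0,
                        "n_cells": n_cells,
                        "nd": True,
                        "missing": True,
                    }
                )
                continue
            gene_counts = np.asarray(counts[idx, cell_mask].todense()).ravel()
            gene_norm = np.asarray(normalised[idx, cell_mask].todense()).ravel()
            n_detected = int((gene_counts > 0).sum())
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "pct_detected": 100.0 * n_detected / n_cells,
                    "mean_norm_expr": float(gene_norm.mean()),
                    "n_cells": n_cells,
                    "nd": n_detected == 0,
                    "missing": False,
                }
            )
    return ClusterGeneStats(table=pd.DataFrame(rows))


def select_clusters_by_markers(
    stats: ClusterGeneStats,
    markers: list[str],
    min_pct: float = 30.0,
    min_mean: float = 0.25,
) -> list[str]:
    """Clusters in which every marker passes both detection thresholds.

    Used e.g. to pick the endothelial cluster by canonical markers.  An
    empty selection warns (it usually means the markers are absent from the
    matrix) but is not an error.
    """
    if not markers:
        raise ValueError("markers must be non-empty")
    selected = []
    for cluster in sorted(stats.table["cluster"].unique()):
        ok = True
        for marker in markers:
            try:
                row = stats.get(marker, cluster)
            except KeyError:
                ok = False
                break
            if row["missing"] or row["pct_detected"] < min_pct or row[
                "mean_norm_expr"
            ] < min_mean:
                ok = False
                break
        if ok:
            selected.append(cluster)
    if not selected:
        warnings.warn(
            "no cluster passed the marker thresholds "
            f"(min_pct={min_pct}, min_mean={min_mean})",
            stacklevel=2,
        )
    return selected
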