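"""Single-cell QC, per-type averaging and the IC overexpression analysis.

The overexpression chain mirrors the single-cell reading of immune gene
clusters: QC-filter the matrix, average each gene within each annotated
cell type, call a gene "overexpressed" in the types whose average strictly
exceeds mean + 0.5 SD across types, split each IC's genes into subclusters
by hierarchical clustering of the binary call vectors, and report each
subcluster's fraction of overexpressed genes per cell type (the dotplot
table).  The differential-expression threshold filter (|logFC| > 0.25 and
Bonferroni-adjusted p < 0.05) runs over a pluggable rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu
from sklearn.metrics import silhouette_score

from .expression import ExpressionMatrix

__all__ = [
    "QCReport",
    "sc_qc_filter",
    "celltype_average",
    "OverexpressionMatrix",
    "overexpression_calls",
    "binary_subcluster",
    "SubclusterTable",
    "overexpression_fractions",
    "rank_sum_de",
    "de_threshold_filter",
]


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    removed_low_gene_cells: int
    removed_low_cell_genes: int
    removed_high_mito_cells: int
    n_cells_out: int
    n_genes_out: int


def _mito_mask(genes, mito_genes=None, prefix: str = "MT-"):
    if mito_genes is not None:
        return genes.isin(list(mito_genes))
    return genes.str.upper().str.startswith(prefix.upper())


def sc_qc_filter(
    sc: ExpressionMatrix,
    min_genes: int = 200,
    min_cells: int = 3,
    max_mito: float = 0.05,
    mito_genes=None,
):
    """Standard single-cell QC with strict thresholds.

    Filters in order: cells expressing fewer than ``min_genes`` genes are
    removed; genes expressed in fewer than ``min_cells`` cells are removed;
    cells whose mitochondrial fraction is not strictly under ``max_mito``
    are removed.  "Expressed" means value > 0.  Mitochondrial genes are
    identified by the ``MT-`` prefix or an explicit list.  Returns
    ``(filtered, QCReport)``; raises with stage-wise counts when nothing
    survives.
    """
    data = sc.data
    n_cells_in, n_genes_in = data.shape[1], data.shape[0]

    expressed = data > 0
    genes_per_cell = expressed.sum(axis=0)
    keep_cells = genes_per_cell >= min_genes
    data = data.loc[:, keep_cells]
    removed_cells_1 = int(n_cells_in - data.shape[1])

    cells_per_gene = (data > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells
    data = data.loc[keep_genes]
    removed_genes = int(n_genes_in - data.shape[0])

    mito = _mito_mask(data.index, mito_genes)
    positive = data.clip(lower=0.0)
    total = positive.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mito_frac = positive.loc[mito].sum(axis=0) / total.replace(0, np.nan)
    mito_frac = mito_frac.fillna(0.0)
    keep_mito = mito_frac < max_mito
    removed_mito = int((~keep_mito).sum())
    data = data.loc[:, keep_mito]

    report = QCReport(
        n_cells_in=n_cells_in,
        n_genes_in=n_genes_in,
        removed_low_gene_cells=removed_cells_1,
        removed_low_cell_genes=removed_genes,
        removed_high_mito_cells=removed_mito,
        n_cells_out=data.shape[1],
        n_genes_out=data.shape[0],
    )
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError(f"QC removed everything: {report}")
    return sc.with_data(data), report


def celltype_average(sc: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Arithmetic mean expression per gene per cell type (working scale)."""
    labels = pd.Series(labels)
    unlabeled = [c for c in sc.data.columns if c not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled cells: {unlabeled[:5]}")
    groups = labels.reindex(sc.data.columns)
    return sc.data.T.groupby(groups).mean().T


@dataclass
class OverexpressionMatrix:
    """Binary genes x cell-types overexpression calls and the per-gene
    thresholds (mean + 0.5 SD across types, sample SD with n-1)."""

    calls: pd.DataFrame
    thresholds: pd.Series

    def __post_init__(self):
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("calls must be binary")


def overexpression_calls(avg: pd.DataFrame, ddof: int = 1) -> OverexpressionMatrix:
    """Call a gene overexpressed in the cell types whose average strictly
    exceeds the gene's across-type mean + 0.5 SD."""
    if avg.shape[1] < 2:
        raise ValueError("overexpression calls need >= 2 cell types")
    mean = avg.mean(axis=1)
    sd = avg.std(axis=1, ddof=ddof)
    thr = mean + 0.5 * sd
    calls = avg.gt(thr, axis=0).astype(int)
    return OverexpressionMatrix(calls=calls, thresholds=thr)


@dataclass
class SubclusterTable:
    """Per-IC gene -> subcluster assignment plus bookkeeping notes."""

    assignments: pd.Series  # gene -> subcluster id (1-based within the IC)
    n_subclusters: int
    note: str = ""

    def __post_init__(self):
        if set(self.assignments.unique()) != set(range(1, self.n_subclusters + 1)):
            raise ValueError("subclusters must partition the genes with contiguous ids")


def binary_subcluster(calls: pd.DataFrame, n_subclusters: int | None = None) -> SubclusterTable:
    """Split one IC's genes into subclusters on their binary call vectors.

    Agglomerative hierarchical clustering (Euclidean distance on 0/1
    vectors, complete linkage), cut at ``n_subclusters``; when None the cut
    maximizes the mean silhouette over 2..min(8, n_genes - 1) (smallest
    count on ties).  All-identical call vectors yield a single subcluster
    with a note.
    """
    if len(calls) < 2:
        raise ValueError("binary subclustering needs >= 2 genes")
    X = calls.to_numpy(dtype=float)
    if (X == X[0]).all():
        return SubclusterTable(
            assignments=pd.Series(1, index=calls.index),
            n_subclusters=1,
            note="all call vectors identical; single subcluster",
        )
    Z = linkage(X, method="complete", metric="euclidean")

    def cut(k):
        raw = fcluster(Z, t=k, criterion="maxclust")
        # relabel by first appearance for determinism
        seen = {}
        out = np.empty_like(raw)
        for i, c in enumerate(raw):
            out[i] = seen.setdefault(c, len(seen) + 1)
        return out

    note = ""
    if n_subclusters is None:
        best = None
        for k in range(2, min(8, len(calls) - 1) + 1):
            lab = cut(k)
            if len(np.unique(lab)) < 2:
                continue
            try:
                s = silhouette_score(X, lab, metric="euclidean")
            except ValueError:
                continue
            if best is None or s > best[0] + 1e-12:
                best = (s, k, lab)
        if best is None:
            lab = cut(2)
            k = len(np.unique(lab))
            note = "silhouette undefined; fell back to a 2-cut"
        else:
            _, k, lab = best
            note = f"auto subcluster count by silhouette (k={k})"
    else:
        lab = cut(n_subclusters)
        k = len(np.unique(lab))
        if k < n_subclusters:
            note = f"requested {n_subclusters} subclusters, tree admits {k}"
    return SubclusterTable(
        assignments=pd.Series(lab, index=calls.index), n_subclusters=int(lab.max()), note=note
    )


def overexpression_fractions(table: SubclusterTable, calls: OverexpressionMatrix) -> pd.DataFrame:
    """Dotplot table: fraction of each subcluster's genes overexpressed in
    each cell type."""
    missing = [g for g in table.assignments.index if g not in calls.calls.index]
    if missing:
        raise ValueError(f"assignments cover genes absent from calls: {missing[:5]}")
    sub = calls.calls.loc[table.assignments.index]
    frac = sub.groupby(table.assignments).mean()
    frac.index = [int(i) for i in frac.index]
    frac.index.name = "subcluster"
    return frac


def rank_sum_de(sc: ExpressionMatrix, labels: pd.Series, group, reference=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression of ``group``
    versus ``reference`` (all other cells by default).

    A pluggable stand-in for model-based single-cell DE tests; logFC is the
    difference of group means on the matrix's working (log-like) scale.
    Returns a per-gene DataFrame with ``logfc`` and ``pval``.
    """
    labels = pd.Series(labels).reindex(sc.data.columns)
    in_group = (labels == group).to_numpy()
    if reference is None:
        in_ref = ~in_group
    else:
        in_ref = (labels == reference).to_numpy()
    if in_group.sum() < 2 or in_ref.sum() < 2:
        raise ValueError("need >= 2 cells per side")
    A = sc.data.loc[:, in_group].to_numpy()
    B = sc.data.loc[:, in_ref].to_numpy()
    _, pvals = mannwhitneyu(A, B, axis=1, alternative="two-sided")
    logfc = A.mean(axis=1) - B.mean(axis=1)
    return pd.DataFrame({"logfc": logfc, "pval": pvals}, index=sc.data.index)


def de_threshold_filter(stats: pd.DataFrame, n_tests: int, logfc_min: float = 0.25, alpha: float = 0.05):
    """Bonferroni threshold filter: keep genes with logFC strictly over
    ``logfc_min`` and adjusted p (p * n_tests, capped at 1) strictly under
    ``alpha``."""
    if n_tests < len(stats):
        raise ValueError(f"n_tests={n_tests} smaller than the {len(stats)} genes tested")
    p = stats["pval"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(p * n_tests, 1.0)
    keep = (stats["logfc"].to_numpy() > logfc_min) & (adj < alpha)
    return list(stats.index[keep])
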