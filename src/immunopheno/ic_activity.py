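"""Immune gene-cluster (IC) activity scoring on bulk expression.

An IC is a predefined set of co-correlated immune-related genes.  Its
per-sample activity is computed as:

1. drop genes with low variance (< 0.05 by default) across samples
   (on the log2-normalized analysis scale);
2. scale each gene's sample vector to [0, 1] after clipping at its 2nd and
   98th percentiles (outlier removal);
3. find the largest group of genes in the cluster that are *pairwise*
   positively correlated with each other — a maximum clique in the
   positive-correlation graph (exact for clusters of up to 40 genes,
   greedy peeling above, with the method recorded);
4. activity(sample) = median of the selected genes' scaled values.

Activities therefore lie in [0, 1] by construction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import ExpressionMatrix

__all__ = [
    "GeneClusterSet",
    "load_gene_clusters",
    "variance_filter",
    "clip_scale_01",
    "largest_positive_corr_group",
    "ActivityMatrix",
    "ICActivityScorer",
    "ic_activity",
]

EXACT_CLIQUE_LIMIT = 40


@dataclass
class GeneClusterSet:
    """Named immune gene clusters (IC1..ICn -> gene lists)."""

    clusters: dict

    def __post_init__(self):
        for name, genes in self.clusters.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes in cluster {name}")

    def __getitem__(self, name):
        return self.clusters[name]

    def items(self):
        return self.clusters.items()

    def names(self):
        return list(self.clusters)


def load_gene_clusters(path) -> GeneClusterSet:
    """Load gene clusters from GMT (name<TAB>desc<TAB>genes...) or JSON."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return GeneClusterSet(json.load(fh))
    clusters = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            clusters[parts[0]] = [g for g in parts[2:] if g]
    return GeneClusterSet(clusters)


def variance_filter(m: ExpressionMatrix, min_var: float = 0.05) -> ExpressionMatrix:
    """Remove genes whose sample variance is strictly below ``min_var``.

    Intended for log2-normalized values (the only scale on which the 0.05
    default is meaningful).  A gene at exactly ``min_var`` is kept.
    """
    if len(m.samples) < 2:
        raise ValueError("variance filter needs >= 2 samples")
    var = m.data.var(axis=1, ddof=1)
    kept = m.data.loc[var >= min_var]
    if kept.empty:
        raise ValueError("variance filter removed all genes")
    return m.with_data(kept)


def clip_scale_01(values, lo_pct: float = 2.0, hi_pct: float = 98.0) -> np.ndarray:
    """Scale one gene's sample vector to [0, 1] with percentile clipping.

    Percentiles use linear interpolation between order statistics.  Values
    at or below the low percentile map to 0, at or above the high
    percentile map to 1, the rest linearly in between.  Raises on a
    degenerate gene (equal percentiles).
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("degenerate gene: fewer than 2 distinct values")
    p_lo, p_hi = np.percentile(values, [lo_pct, hi_pct])
    if p_lo == p_hi:
        raise ValueError("degenerate gene: clipping percentiles coincide")
    scaled = (values - p_lo) / (p_hi - p_lo)
    return np.clip(scaled, 0.0, 1.0)


def _positive_corr_graph(scaled: pd.DataFrame) -> nx.Graph:
    genes = list(scaled.index)
    R = np.corrcoef(scaled.to_numpy(dtype=float))
    R = np.atleast_2d(R)
    G = nx.Graph()
    G.add_nodes_from(genes)
    for i, j in itertools.combinations(range(len(genes)), 2):
        if R[i, j] > 0:
            G.add_edge(genes[i], genes[j])
    return G


def _greedy_peel(G: nx.Graph):
    """Iteratively drop the gene with the most non-positive correlations
    (lexicographically last on ties) until all pairs are positive."""
    nodes = sorted(G.nodes)
    while True:
        n = len(nodes)
        missing = {
            v: n - 1 - sum(1 for u in nodes if u != v and G.has_edge(u, v))
            for v in nodes
        }
        worst = max(missing.values())
        if worst == 0:
            return nodes
        candidates = [v for v in nodes if missing[v] == worst]
        nodes.remove(candidates[-1])


def largest_positive_corr_group(scaled: pd.DataFrame):
    """Maximum-cardinality gene set with all pairwise correlations > 0.

    ``scaled`` is genes x samples (already clip-scaled).  Exact maximum
    clique (enumeration of maximal cliques) for up to
    ``EXACT_CLIQUE_LIMIT`` genes with lexicographic tie-break; greedy
    peeling above.  When no positive pair exists, the single gene with the
    highest mean correlation to the others is returned.

    Returns ``(genes, method)`` with method in {"exact", "greedy",
    "singleton"}.
    """
    genes = list(scaled.index)
    if len(genes) == 1:
        return genes, "exact"
    G = _positive_corr_graph(scaled)
    if G.number_of_edges() == 0:
        R = np.corrcoef(scaled.to_numpy(dtype=float))
        mean_r = (R.sum(axis=1) - 1.0) / (len(genes) - 1)
        best = sorted(zip(-mean_r, genes))[0][1]
        return [best], "singleton"
    if len(genes) <= EXACT_CLIQUE_LIMIT:
        best = None
        for clique in nx.find_cliques(G):
            key = (-len(clique), tuple(sorted(clique)))
            if best is None or key < best[0]:
                best = (key, sorted(clique))
        return best[1], "exact"
    return _greedy_peel(G), "greedy"


@dataclass
class ActivityMatrix:
    """ICs x samples activities in [0, 1] plus the selected gene groups."""

    data: pd.DataFrame
    selected_genes: dict
    methods: dict
    undefined: list = field(default_factory=list)

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        finite = ~np.isnan(vals)
        if (vals[finite] < -1e-12).any() or (vals[finite] > 1 + 1e-12).any():
            raise ValueError("activities must lie in [0, 1]")


class ICActivityScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style scorer: fit on a bulk matrix, transform to
    IC x sample activities.

    Parameters
    ----------
    gene_clusters : GeneClusterSet or dict
    min_var : float, default=0.05
    lo_pct, hi_pct : clipping percentiles, default 2 / 98.

    ``fit`` selects each IC's largest positively-intercorrelated gene group
    on the fitted samples; ``transform`` evaluates the scaled medians.
    """

    def __init__(self, gene_clusters=None, min_var: float = 0.05, lo_pct: float = 2.0, hi_pct: float = 98.0):
        self.gene_clusters = gene_clusters
        self.min_var = min_var
        self.lo_pct = lo_pct
        self.hi_pct = hi_pct

    def _clusters(self):
        gc = self.gene_clusters
        if gc is None:
            raise ValueError("gene_clusters is required")
        return gc if isinstance(gc, GeneClusterSet) else GeneClusterSet(dict(gc))

    def fit(self, X, y=None):
        """X: genes x samples DataFrame on the log2 analysis scale."""
        X = pd.DataFrame(X)
        self._columns = X.columns
        self.selected_genes_ = {}
        self.methods_ = {}
        self.undefined_ = []
        self._scaled = {}
        for name, genes in self._clusters().items():
            sub = X.loc[[g for g in genes if g in X.index]]
            if len(sub):
                var = sub.var(axis=1, ddof=1)
                sub = sub.loc[var >= self.min_var]
            scaled_rows = {}
            for g in sub.index:
                try:
                    scaled_rows[g] = clip_scale_01(
                        sub.loc[g].to_numpy(), self.lo_pct, self.hi_pct
                    )
                except ValueError:
                    continue  # degenerate gene: excluded from the group search
            if not scaled_rows:
                self.undefined_.append(name)
                continue
            scaled = pd.DataFrame(scaled_rows, index=sub.columns).T
            group, method = largest_positive_corr_group(scaled)
            self.selected_genes_[name] = group
            self.methods_[name] = method
            self._scaled[name] = scaled.loc[group]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Activities of the fitted samples (the statistic is defined on
        the cohort it was scaled on).  Undefined ICs yield NaN rows."""
        names = list(self.selected_genes_) + self.undefined_
        out = pd.DataFrame(np.nan, index=names, columns=self._columns)
        for name, scaled in self._scaled.items():
            out.loc[name] = scaled.median(axis=0)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(None)


def ic_activity(bulk: ExpressionMatrix, ics, min_var: float = 0.05) -> ActivityMatrix:
    """Functional wrapper: IC activities for a log2-normalized bulk matrix."""
    scorer = ICActivityScorer(gene_clusters=ics, min_var=min_var)
    data = scorer.fit_transform(bulk.data)
    return ActivityMatrix(
        data=data,
        selected_genes=scorer.selected_genes_,
        methods=scorer.methods_,
        undefined=scorer.undefined_,
    )
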