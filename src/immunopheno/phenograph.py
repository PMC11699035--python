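"""PhenoGraph-style phenoclustering with the two-round CD45 scheme.

``PhenoGraphClusterer`` is the single-round estimator: exact kNN graph,
Jaccard re-weighting, Louvain modularity maximization.  The two-round
workflow used for CD45-enriched cytometry cohorts first clusters all merged
events, removes clusters whose median CD45 falls below a criterion (debris
and non-immune material), then re-clusters the surviving events.  Cluster
robustness is scored by a clusterboot-style bootstrap: resample events with
replacement, re-cluster, and record each original cluster's best Jaccard
overlap with any new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics.cluster import contingency_matrix

from .events import EventTable
from .graph import build_knn_graph
from .louvain import Partition, louvain_partition

__all__ = [
    "PhenoGraphClusterer",
    "TwoRoundPhenoClusterer",
    "PhenoResult",
    "two_round_cluster",
    "cluster_stability",
    "embed_coordinates",
]


class PhenoGraphClusterer(BaseEstimator, ClusterMixin):
    """kNN-Jaccard-Louvain clustering of events.

    Parameters
    ----------
    k : int, default=60
        Neighbor count for the kNN graph.
    resolution : float, default=1.0
        Louvain resolution.
    n_restarts : int, default=4
        Seeded Louvain restarts; best modularity wins.
    random_state : int, default=0

    Attributes
    ----------
    labels_ : ndarray of shape (n_events,)
    modularity_ : float
    graph_ : KnnGraph
    """

    def __init__(self, k: int = 60, resolution: float = 1.0, n_restarts: int = 4, random_state: int = 0):
        self.k = k
        self.resolution = resolution
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.graph_ = build_knn_graph(X, k=self.k, seed=self.random_state)
        part = louvain_partition(
            self.graph_,
            resolution=self.resolution,
            seed=self.random_state,
            n_restarts=self.n_restarts,
        )
        self.labels_ = part.labels
        self.modularity_ = part.modularity
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class PhenoResult:
    """Result of the two-round clustering scheme.

    ``round2_labels`` is defined only where ``kept_mask`` is True (-1
    elsewhere); ``stability`` maps round-2 cluster id to its mean bootstrap
    Jaccard coefficient, when scored.
    """

    round1_labels: np.ndarray
    kept_mask: np.ndarray
    round2_labels: np.ndarray
    round1_modularity: float
    round2_modularity: float
    parameters: dict = field(default_factory=dict)
    stability: dict | None = None

    def __post_init__(self):
        if ((self.round2_labels >= 0) != self.kept_mask).any():
            raise ValueError("round2 labels must be defined exactly on kept events")
        if self.stability is not None:
            for c, s in self.stability.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"stability of cluster {c} out of [0, 1]")


class TwoRoundPhenoClusterer(BaseEstimator, ClusterMixin):
    """Two-round phenoclustering with CD45-low cluster filtering.

    Round 1 clusters all events.  Clusters whose median CD45 intensity falls
    below the criterion are removed with all their events; the survivors are
    re-clustered (round 2).

    Parameters
    ----------
    cd45_channel : str or int
        Column name (DataFrame input) or index (array input) of the
        CD45-like channel.
    cd45_mode : {"quantile", "absolute"}, default="quantile"
        "quantile": drop clusters whose median CD45 lies strictly below
        the ``cd45_threshold`` quantile of the per-cluster medians, where
        the quantile is taken as the lower order statistic (index
        ``floor(q * (n_clusters - 1))`` of the sorted medians).  Because
        the cut coincides with an actual cluster median and the
        comparison is strict, a cluster tying the cut always survives —
        the rule cannot cut through the middle of a population whose
        round-1 clusters tie near the quantile.  Scale-free default for
        fluorescence data.  "absolute": drop clusters with median
        strictly below the given value (e.g. 0.5 on the arcsinh scale
        for mass cytometry).
    cd45_threshold : float, default=0.25

    Attributes
    ----------
    round1_labels_, kept_mask_, labels_ (round-2 labels, -1 for removed),
    result_ : PhenoResult
    """

    def __init__(
        self,
        cd45_channel="CD45",
        cd45_mode: str = "quantile",
        cd45_threshold: float = 0.25,
        k: int = 60,
        resolution: float = 1.0,
        n_restarts: int = 4,
        random_state: int = 0,
    ):
        self.cd45_channel = cd45_channel
        self.cd45_mode = cd45_mode
        self.cd45_threshold = cd45_threshold
        self.k = k
        self.resolution = resolution
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _cd45_values(self, X):
        if isinstance(X, pd.DataFrame):
            if self.cd45_channel not in X.columns:
                raise KeyError(f"CD45 channel {self.cd45_channel!r} not in data")
            return X[self.cd45_channel].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X[:, int(self.cd45_channel)]

    def fit(self, X, y=None):
        if self.cd45_mode not in ("quantile", "absolute"):
            raise ValueError(f"unknown cd45_mode {self.cd45_mode!r}")
        cd45 = self._cd45_values(X)
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)

        base = PhenoGraphClusterer(
            k=self.k,
            resolution=self.resolution,
            n_restarts=self.n_restarts,
            random_state=self.random_state,
        )
        r1 = base.fit(Xa)
        labels1 = r1.labels_

        medians = np.array(
            [np.median(cd45[labels1 == c]) for c in range(labels1.max() + 1)]
        )
        if self.cd45_mode == "quantile":
            cut = np.quantile(medians, self.cd45_threshold, method="lower")
        else:
            cut = self.cd45_threshold
        low = medians < cut
        if low.all():
            raise ValueError("no CD45-positive clusters: criterion removes all clusters")
        kept = ~low[labels1]

        r2 = PhenoGraphClusterer(
            k=self.k,
            resolution=self.resolution,
            n_restarts=self.n_restarts,
            random_state=self.random_state,
        ).fit(Xa[kept])

        labels2 = np.full(len(labels1), -1, dtype=np.int64)
        labels2[kept] = r2.labels_

        self.round1_labels_ = labels1
        self.kept_mask_ = kept
        self.labels_ = labels2
        self.result_ = PhenoResult(
            round1_labels=labels1,
            kept_mask=kept,
            round2_labels=labels2,
            round1_modularity=r1.modularity_,
            round2_modularity=r2.modularity_,
            parameters={
                "k": self.k,
                "resolution": self.resolution,
                "random_state": self.random_state,
                "cd45_mode": self.cd45_mode,
                "cd45_threshold": self.cd45_threshold,
                "cd45_cut_value": float(cut),
            },
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def two_round_cluster(
    merged: EventTable,
    k: int = 60,
    cd45_channel: str = "CD45",
    cd45_mode: str = "quantile",
    cd45_threshold: float = 0.25,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 4,
) -> PhenoResult:
    """Functional wrapper over :class:`TwoRoundPhenoClusterer` for tables."""
    if merged.transform_state == "raw":
        raise ValueError("two_round_cluster expects a transformed table")
    est = TwoRoundPhenoClusterer(
        cd45_channel=cd45_channel,
        cd45_mode=cd45_mode,
        cd45_threshold=cd45_threshold,
        k=k,
        resolution=resolution,
        n_restarts=n_restarts,
        random_state=seed,
    )
    est.fit(merged.data)
    return est.result_


def _best_jaccard(orig_mask_labels, new_labels):
    """Per original cluster, max Jaccard overlap with any new cluster."""
    cont = contingency_matrix(orig_mask_labels, new_labels)
    sizes_o = cont.sum(axis=1)[:, None]
    sizes_n = cont.sum(axis=0)[None, :]
    jac = cont / (sizes_o + sizes_n - cont)
    return jac.max(axis=1)


def cluster_stability(
    X,
    labels,
    n_boot: int = 50,
    k: int = 60,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 2,
):
    """Bootstrap-Jaccard stability of each cluster (clusterboot-style).

    For each of ``n_boot`` resamples of events with replacement the data is
    re-clustered with the same parameters; a cluster's score for one
    replicate is the maximum Jaccard coefficient between its membership and
    any new cluster, computed over the resampled event draws.  The final
    score is the mean over replicates.  Clusters entirely absent from a
    resample skip that replicate; the number of contributing replicates is
    reported.

    Returns
    -------
    scores : dict cluster -> mean Jaccard in [0, 1]
    n_used : dict cluster -> number of contributing replicates
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels must cover events")
    clusters = np.unique(labels)
    n = len(X)
    rng = np.random.default_rng(seed)
    sums = {c: 0.0 for c in clusters}
    used = {c: 0 for c in clusters}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_labels = labels[idx]
        new = PhenoGraphClusterer(
            k=min(k, n - 1),
            resolution=resolution,
            n_restarts=n_restarts,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit_predict(X[idx])
        present = np.unique(boot_labels)
        best = _best_jaccard(boot_labels, new)
        for ci, c in enumerate(present):
            sums[c] += best[ci]
            used[c] += 1
    scores = {int(c): (sums[c] / used[c] if used[c] else float("nan")) for c in clusters}
    return scores, {int(c): used[c] for c in clusters}


def embed_coordinates(X, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """2-D embedding for visualization via a pluggable backend.

    ``tsne`` uses scikit-learn's TSNE; ``umap`` requires the optional
    umap-learn plug-in.  No algorithmic claims are made about either; the
    coordinates are presentation output.
    """
    X = np.asarray(X, dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        emb = TSNE(
            n_components=2,
            random_state=seed,
            perplexity=min(30.0, max(2.0, (len(X) - 1) / 3.0)),
            init="pca",
        )
        return emb.fit_transform(X)
    if method == "umap":
        try:
            import umap
        except ImportError as exc:
            raise ImportError(
                "umap backend requested but the umap-learn plug-in is not installed"
            ) from exc
        return umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


# A cluster is accepted as robust when its mean bootstrap-Jaccard stability
# strictly exceeds this criterion.
STABILITY_CRITERION = 0.75


def is_stable(score: float) -> bool:
    return score > STABILITY_CRITERION
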