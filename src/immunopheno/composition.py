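"""Phenocluster annotation, composition matrices and correlation reports.

Phenoclusters are summarized by per-channel median intensity discretized to
lo/mid/hi levels (tertiles of the per-cluster medians within each channel)
and annotated through a user-editable marker-rule table.  Sample x cluster
composition fractions and their Pearson/Spearman correlations (with exact
t-distribution p-values) reproduce the sample- and cell-type-level
correlation analyses of cytometry immunophenotyping studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerSummary",
    "CompositionMatrix",
    "CorrelationReport",
    "DEFAULT_MARKER_RULES",
    "load_marker_rules",
    "summarize_markers",
    "composition",
    "correlate",
    "group_to_celltypes",
    "correlation_pvalue",
]

_P_FLOOR = 2.2e-16


@dataclass
class MarkerSummary:
    cluster: int
    medians: dict
    levels: dict  # channel -> "lo" | "mid" | "hi"
    annotation: str


# Default marker-rule table: ordered list of (conditions, annotation); the
# first rule whose conditions (channel -> required level(s)) all hold wins.
# Mirrors the phenotype logic of CD45-enriched brain-tumor infiltrates,
# including the noncanonical myeloid subsets.
DEFAULT_MARKER_RULES = [
    ({"CD3": "hi", "CD14": ("mid", "hi"), "CD66b": ("mid", "hi")}, "CD3+ myeloid"),
    ({"CD19": "hi", "CD14": ("mid", "hi")}, "CD19+ myeloid"),
    ({"CD66b": "hi"}, "neutrophil"),
    ({"CD3": "hi", "CD4": "hi"}, "CD4 T cell"),
    ({"CD3": "hi", "CD8": "hi"}, "CD8 T cell"),
    ({"CD3": "hi", "CD4": ("lo", "mid"), "CD8": ("lo", "mid")}, "double-negative T cell"),
    ({"CD19": "hi"}, "B cell"),
    ({"CD14": "hi", "CD45": ("mid", "hi")}, "MDM"),
    ({"CD14": ("mid", "hi"), "CD45": "lo"}, "microglia"),
    ({"CD45": "lo"}, "CD45-low"),
]


def load_marker_rules(path):
    """Load a marker-rule table from YAML: a list of
    ``{when: {channel: level-or-list}, label: text}`` entries."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        when = {ch: v if isinstance(v, str) else tuple(v) for ch, v in entry["when"].items()}
        rules.append((when, entry["label"]))
    return rules


def _apply_rules(levels: dict, rules) -> str:
    for conditions, label in rules:
        ok = True
        for ch, req in conditions.items():
            allowed = (req,) if isinstance(req, str) else tuple(req)
            if levels.get(ch) not in allowed:
                ok = False
                break
        if ok:
            return label
    return "unclassified"


def summarize_markers(
    events, labels, rules=None, min_spread_frac: float = 0.2
) -> list[MarkerSummary]:
    """Per-cluster marker summaries with lo/mid/hi levels and annotations.

    ``events`` may be an EventTable or a DataFrame of transformed
    intensities; ``labels`` is the per-event cluster assignment.  Levels are
    assigned per channel by tertiles of the per-cluster medians: strictly
    below the lower tertile is "lo", strictly above the upper tertile is
    "hi", otherwise "mid".

    Tertile levels are relative, so a channel on which no cluster carries
    real signal would still hand out spurious "hi" labels.  Channels whose
    cluster-median spread is below ``min_spread_frac`` of the widest
    channel's spread are treated as non-informative and report "mid" for
    every cluster.
    """
    data = events.data if hasattr(events, "data") else events
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels must cover events")
    if rules is None:
        rules = DEFAULT_MARKER_RULES
    clusters = np.unique(labels)
    med = data.groupby(labels).median()
    for c in clusters:
        if (labels == c).sum() == 0:  # pragma: no cover - unreachable
            raise ValueError(f"empty cluster {c}")
    t1 = med.quantile(1 / 3)
    t2 = med.quantile(2 / 3)
    spread = med.max() - med.min()
    informative = spread >= min_spread_frac * spread.max()
    summaries = []
    for c in clusters:
        row = med.loc[c]
        levels = {}
        for ch in data.columns:
            if not informative[ch]:
                levels[ch] = "mid"
            elif row[ch] < t1[ch]:
                levels[ch] = "lo"
            elif row[ch] > t2[ch]:
                levels[ch] = "hi"
            else:
                levels[ch] = "mid"
        summaries.append(
            MarkerSummary(
                cluster=int(c),
                medians=row.to_dict(),
                levels=levels,
                annotation=_apply_rules(levels, rules),
            )
        )
    return summaries


@dataclass
class CompositionMatrix:
    """Samples x clusters (or cell types) fraction matrix.

    ``undefined_samples`` lists samples with a zero denominator (their rows
    are NaN, never silently zero).
    """

    data: pd.DataFrame
    denominator: str = "cd45_kept"
    undefined_samples: list = field(default_factory=list)

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        finite = ~np.isnan(vals)
        if ((vals < -1e-12) & finite).any() or ((vals > 1 + 1e-12) & finite).any():
            raise ValueError("fractions must lie in [0, 1]")
        if self.denominator == "cd45_kept":
            sums = np.nansum(vals, axis=1)
            ok = np.array([s in self.undefined_samples for s in self.data.index])
            if (np.abs(sums[~ok] - 1.0) > 1e-9).any():
                raise ValueError("rows must sum to 1 for the cd45_kept denominator")


def composition(
    labels,
    provenance,
    denominator: str = "cd45_kept",
    totals: dict | None = None,
) -> CompositionMatrix:
    """Sample x cluster fractions of events.

    ``denominator="cd45_kept"`` divides by each sample's labeled (kept)
    events, so rows sum to 1; ``denominator="all_events"`` divides by the
    sample's pre-filter event totals, which must be supplied via
    ``totals``.
    """
    labels = np.asarray(labels)
    provenance = np.asarray(provenance)
    if len(labels) != len(provenance):
        raise ValueError("provenance must cover all labeled events")
    if denominator not in ("cd45_kept", "all_events"):
        raise ValueError(f"unknown denominator {denominator!r}")
    counts = pd.crosstab(pd.Series(provenance, name="sample"), pd.Series(labels, name="cluster"))
    if denominator == "all_events":
        if totals is None:
            raise ValueError("denominator='all_events' requires per-sample totals")
        denom = pd.Series(totals).reindex(counts.index)
        if denom.isna().any():
            raise ValueError("totals missing for some samples")
    else:
        denom = counts.sum(axis=1)
    undefined = list(counts.index[denom == 0])
    denom = denom.replace(0, np.nan)
    frac = counts.div(denom, axis=0)
    return CompositionMatrix(data=frac, denominator=denominator, undefined_samples=undefined)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a correlation via t = r*sqrt(n-2)/sqrt(1-r^2)
    on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationReport:
    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    p_display: pd.DataFrame = None  # strings; "< 2.2e-16" below the floor
    degenerate: list = field(default_factory=list)  # zero-variance vectors

    def __post_init__(self):
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method {self.method!r}")


def correlate(m, axis: str = "celltypes", method: str = "pearson") -> CorrelationReport:
    """Pairwise correlations of composition fractions with two-sided
    t-distribution p-values.

    ``axis="celltypes"`` correlates the column vectors across samples
    (cluster-vs-cluster frequencies); ``axis="samples"`` correlates sample
    rows across clusters.  Spearman applies the same t approximation to the
    rank correlation.  Zero-variance vectors yield NaN correlations and are
    listed in ``degenerate``.
    """
    data = m.data if isinstance(m, CompositionMatrix) else pd.DataFrame(m)
    if axis == "samples":
        data = data.T
    elif axis != "celltypes":
        raise ValueError(f"unknown axis {axis!r}")
    data = data.dropna(axis=0, how="any")
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 observations per pair")
    X = data.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sd = X.std(axis=0)
    degenerate = [c for c, s in zip(data.columns, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    np.fill_diagonal(R, 1.0)
    k = R.shape[0]
    P = np.empty_like(R)
    for i in range(k):
        for j in range(k):
            P[i, j] = np.nan if np.isnan(R[i, j]) else correlation_pvalue(R[i, j], n)
    np.fill_diagonal(P, 0.0)
    cols = data.columns
    p_df = pd.DataFrame(P, index=cols, columns=cols)
    disp = p_df.map(
        lambda p: "NA" if np.isnan(p) else (f"< {_P_FLOOR:g}" if p < _P_FLOOR else f"{p:.4g}")
    )
    return CorrelationReport(
        method=method,
        r=pd.DataFrame(R, index=cols, columns=cols),
        p=p_df,
        n=n,
        p_display=disp,
        degenerate=degenerate,
    )


def group_to_celltypes(comp: CompositionMatrix, mapping: dict) -> CompositionMatrix:
    """Sum cluster fractions into cell-type fractions.

    ``mapping`` must cover every cluster column; row sums are preserved
    exactly.
    """
    missing = [c for c in comp.data.columns if c not in mapping]
    if missing:
        raise KeyError(f"no cell-type mapping for clusters {missing}")
    grouped = comp.data.T.groupby([mapping[c] for c in comp.data.columns]).sum().T
    return CompositionMatrix(
        data=grouped,
        denominator=comp.denominator,
        undefined_samples=list(comp.undefined_samples),
    )


def relabel_partition(labels, mapping: dict):
    """Relabel a per-event cluster assignment to cell types."""
    labels = np.asarray(labels)
    missing = sorted({int(c) for c in np.unique(labels) if c not in mapping})
    if missing:
        raise KeyError(f"no cell-type mapping for clusters {missing}")
    return np.asarray([mapping[int(c)] for c in labels], dtype=object)
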