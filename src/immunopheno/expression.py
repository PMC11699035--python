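"""Bulk expression containers and normalization (TPM, quantile, log2).

The normalization flags in ``norm_state`` are ordered: tpm -> quantile ->
log2, the preprocessing chain applied to both bulk samples and purified
reference profiles before deconvolution and gene-module scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExpressionMatrix",
    "tpm_normalize",
    "quantile_normalize",
    "log2_transform",
    "QuantileNormalizer",
]

_NORM_ORDER = ("tpm", "quantile", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with its normalization state.

    ``gene_lengths`` (bases) is required for TPM normalization of raw
    counts and indexed like ``data``.
    """

    data: pd.DataFrame
    norm_state: tuple = ()
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        order = [s for s in _NORM_ORDER if s in self.norm_state]
        if tuple(order) != tuple(self.norm_state):
            raise ValueError(
                f"norm_state must follow the order tpm -> quantile -> log2, got {self.norm_state}"
            )
        if "log2" not in self.norm_state and (self.data.to_numpy() < 0).any():
            raise ValueError("negative values are only permitted after log2")

    @property
    def genes(self):
        return self.data.index

    @property
    def samples(self):
        return self.data.columns

    def with_data(self, data: pd.DataFrame, add_state: str | None = None):
        state = self.norm_state + ((add_state,) if add_state else ())
        return replace(self, data=data, norm_state=state)


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million: rate_g = count_g / length_kb_g, scaled so
    each sample sums to 1e6."""
    if m.norm_state:
        raise ValueError("tpm_normalize expects raw counts")
    if m.gene_lengths is None:
        raise ValueError("tpm_normalize requires gene_lengths")
    missing = m.data.index.difference(m.gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]!r}")
    lengths = m.gene_lengths.reindex(m.data.index).to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = m.data.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    totals = rate.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"zero library: sample {m.data.columns[zero[0]]!r}")
    tpm = rate / totals * 1e6
    return m.with_data(pd.DataFrame(tpm, index=m.data.index, columns=m.data.columns), "tpm")


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization across samples (columns of genes x samples).

    Each sample's sorted values are replaced by the cross-sample mean of
    sorted values, mapped back by rank; tied values receive the mean of the
    reference values over their tied rank range (the standard
    deterministic convention).  The transformer is stateless in the
    scikit-learn sense: ``fit`` records the reference distribution of the
    fitted matrix, ``transform`` maps new columns onto it.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("quantile normalization needs >= 2 samples")
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        ref = self.reference_
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            col = X[:, j]
            ranks = rankdata(col, method="average")  # 1-based, .5 on ties
            lo = np.floor(ranks - 1).astype(int)
            hi = np.ceil(ranks - 1).astype(int)
            mapped = 0.5 * (ref[lo] + ref[hi])
            # exact tie convention: average the reference over the full tied range
            order = np.argsort(col, kind="stable")
            sorted_col = col[order]
            boundaries = np.flatnonzero(np.diff(sorted_col) != 0)
            starts = np.concatenate([[0], boundaries + 1])
            ends = np.concatenate([boundaries, [len(col) - 1]])
            csum = np.concatenate([[0.0], np.cumsum(ref)])
            for s, e in zip(starts, ends):
                if e > s:
                    mean_ref = (csum[e + 1] - csum[s]) / (e - s + 1)
                    mapped[order[s : e + 1]] = mean_ref
            out[:, j] = mapped
        return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples against their own mean distribution."""
    qn = QuantileNormalizer().fit(m.data.to_numpy(dtype=float))
    out = qn.transform(m.data.to_numpy(dtype=float))
    return m.with_data(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), "quantile"
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount)."""
    if "log2" in m.norm_state:
        raise ValueError("matrix is already log2-transformed")
    out = np.log2(m.data.to_numpy(dtype=float) + pseudocount)
    return m.with_data(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), "log2"
    )
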