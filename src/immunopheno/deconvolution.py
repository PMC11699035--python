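"""Reference-based cell-type deconvolution of bulk expression.

A bulk sample's expression vector (restricted to immune-related genes) is
regressed on purified cell-type reference medians with elastic-net
regularization (mixing parameter alpha = 0.25 by default, matching the
convention for this analysis); the penalty weight lambda is chosen per
sample by seeded 10-fold cross-validation over genes, stratified by
expression decile.

The estimator follows the scikit-learn decomposition convention:
``fit`` stores the reference design (``components_``: cell types x genes),
``transform`` maps samples x genes expression onto samples x cell-types
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet

from .expression import ExpressionMatrix

__all__ = ["ReferencePanel", "build_reference", "DeconvResult", "ReferenceDeconvolver", "deconvolve"]


@dataclass
class ReferencePanel:
    """Genes x cell-types median reference built from purified samples."""

    medians: pd.DataFrame
    n_samples: dict
    restriction: list | None = None
    norm_state: tuple = ()

    def __post_init__(self):
        for t, n in self.n_samples.items():
            if n < 1:
                raise ValueError(f"cell type {t} has no reference samples")
        if self.restriction is not None:
            missing = set(self.restriction) - set(self.medians.index)
            if missing:
                raise ValueError(
                    f"restriction genes absent from the panel: {sorted(missing)[:5]}"
                )


def build_reference(
    purified: ExpressionMatrix, type_labels: dict, restriction=None
) -> ReferencePanel:
    """Median expression per gene per cell type over purified samples.

    ``type_labels`` maps each sample id to its cell type; every sample must
    be labeled.  Medians use the mean-of-middle convention for even counts.
    """
    unlabeled = [s for s in purified.samples if s not in type_labels]
    if unlabeled:
        raise ValueError(f"unlabeled purified samples: {unlabeled}")
    groups = pd.Series({s: type_labels[s] for s in purified.samples})
    medians = purified.data.T.groupby(groups).median().T
    counts = groups.value_counts().to_dict()
    return ReferencePanel(
        medians=medians,
        n_samples=counts,
        restriction=list(restriction) if restriction is not None else None,
        norm_state=purified.norm_state,
    )


@dataclass
class DeconvResult:
    """Per-sample elastic-net coefficients and the CV-chosen lambdas."""

    coefficients: pd.DataFrame  # samples x cell types
    alpha: float
    lambdas: pd.Series  # per sample
    intercepts: pd.Series
    n_folds: int
    seed: int
    n_genes: int
    scale: str = "linear"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if (self.lambdas <= 0).any():
            raise ValueError("lambda must be > 0")

    def proportions(self) -> pd.DataFrame:
        """Derived view: coefficients clipped at 0 and renormalized to sum
        to 1 per sample.  Clearly a post-hoc projection of the raw
        regression coefficients onto the simplex."""
        clipped = self.coefficients.clip(lower=0.0)
        sums = clipped.sum(axis=1).replace(0, np.nan)
        return clipped.div(sums, axis=0)


def _decile_stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Fold ids balanced across expression deciles (round-robin within
    decile after a seeded shuffle)."""
    n = len(y)
    deciles = np.minimum((np.argsort(np.argsort(y)) * 10) // n, 9)
    folds = np.empty(n, dtype=int)
    next_fold = 0
    for d in range(10):
        idx = np.flatnonzero(deciles == d)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            folds[i] = next_fold
            next_fold = (next_fold + 1) % n_folds
    return folds


class ReferenceDeconvolver(BaseEstimator, TransformerMixin):
    """Elastic-net regression of bulk samples on cell-type references.

    Parameters
    ----------
    alpha : float, default=0.25
        Elastic-net mixing parameter (1 = lasso, 0 = ridge).
    n_folds : int, default=10
        Cross-validation folds over genes for the lambda choice.
    n_lambdas : int, default=60
        Log-spaced lambda path length (from the data-derived lambda_max
        down to ``lambda_max * 1e-4``).
    fit_intercept : bool, default=True
    design_scale : {"linear", "log2"}, default="linear"
        Scale of the regression design.  "linear" un-logs log2-flagged
        inputs (2**x - 1) so that mixing weights of linear-scale mixtures
        are recovered directly; "log2" regresses the log2 values as-is.
    random_state : int, default=0

    Attributes
    ----------
    components_ : ndarray (n_cell_types, n_genes)
    cell_types_, genes_ : the design labels
    """

    def __init__(
        self,
        alpha: float = 0.25,
        n_folds: int = 10,
        n_lambdas: int = 60,
        fit_intercept: bool = True,
        design_scale: str = "linear",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.fit_intercept = fit_intercept
        self.design_scale = design_scale
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: genes x cell-types reference design (DataFrame), already on
        the regression scale chosen by the caller via ``design_scale``."""
        X = pd.DataFrame(X)
        self.genes_ = list(X.index)
        self.cell_types_ = list(X.columns)
        self.components_ = X.to_numpy(dtype=float).T
        return self

    def _lambda_grid(self, D: np.ndarray, y: np.ndarray):
        n = len(y)
        yc = y - y.mean() if self.fit_intercept else y
        Dc = D - D.mean(axis=0) if self.fit_intercept else D
        l1 = max(self.alpha, 1e-3)
        lam_max = np.abs(Dc.T @ yc).max() / (n * l1)
        lam_max = max(lam_max, 1e-12)
        return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), self.n_lambdas)

    def _fit_one(self, D: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        lams = self._lambda_grid(D, y)
        folds = _decile_stratified_folds(y, self.n_folds, rng)
        cv_err = np.zeros(len(lams))
        for f in range(self.n_folds):
            train = folds != f
            test = ~train
            for li, lam in enumerate(lams):
                model = ElasticNet(
                    alpha=lam,
                    l1_ratio=self.alpha,
                    fit_intercept=self.fit_intercept,
                    max_iter=5000,
                )
                model.fit(D[train], y[train])
                resid = y[test] - model.predict(D[test])
                cv_err[li] += resid @ resid
        best = int(np.argmin(cv_err))
        lam = lams[best]
        final = ElasticNet(
            alpha=lam,
            l1_ratio=self.alpha,
            fit_intercept=self.fit_intercept,
            max_iter=50000,
        )
        final.fit(D, y)
        return final.coef_, float(lam), float(final.intercept_)

    def transform(self, X):
        """X: samples x genes (aligned with ``genes_``); returns samples x
        cell-types coefficients."""
        X = np.asarray(X, dtype=float)
        D = self.components_.T  # genes x types
        rng = np.random.default_rng(self.random_state)
        coefs = np.empty((X.shape[0], D.shape[1]))
        self.lambdas_ = np.empty(X.shape[0])
        self.intercepts_ = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            coefs[i], self.lambdas_[i], self.intercepts_[i] = self._fit_one(
                D, X[i], rng
            )
        return coefs


def _to_design_scale(values: np.ndarray, norm_state, design_scale: str) -> np.ndarray:
    if design_scale == "linear" and "log2" in norm_state:
        return np.exp2(values) - 1.0
    return values


def deconvolve(
    bulk: ExpressionMatrix,
    panel: ReferencePanel,
    alpha: float = 0.25,
    folds: int = 10,
    seed: int = 0,
    fit_intercept: bool = True,
    design_scale: str = "linear",
) -> DeconvResult:
    """Deconvolve bulk samples against a reference panel.

    Genes are restricted to the panel's immune-related restriction set when
    present; bulk and panel must share those genes and be normalized
    identically.
    """
    genes = panel.restriction if panel.restriction is not None else list(panel.medians.index)
    genes = [g for g in genes if g in bulk.genes]
    if not genes:
        raise ValueError("no overlap between restriction genes and bulk genes")
    if len(genes) < folds:
        raise ValueError(f"fewer genes ({len(genes)}) than folds ({folds})")
    if bulk.norm_state != panel.norm_state:
        raise ValueError(
            f"bulk normalization {bulk.norm_state} differs from panel {panel.norm_state}"
        )
    ref = panel.medians.loc[genes]
    B = bulk.data.loc[genes]
    ref_vals = _to_design_scale(ref.to_numpy(dtype=float), panel.norm_state, design_scale)
    bulk_vals = _to_design_scale(B.to_numpy(dtype=float), bulk.norm_state, design_scale)

    est = ReferenceDeconvolver(
        alpha=alpha,
        n_folds=folds,
        fit_intercept=fit_intercept,
        design_scale=design_scale,
        random_state=seed,
    )
    est.fit(pd.DataFrame(ref_vals, index=genes, columns=ref.columns))
    coefs = est.transform(bulk_vals.T)
    samples = list(bulk.samples)
    return DeconvResult(
        coefficients=pd.DataFrame(coefs, index=samples, columns=ref.columns),
        alpha=alpha,
        lambdas=pd.Series(est.lambdas_, index=samples),
        intercepts=pd.Series(est.intercepts_, index=samples),
        n_folds=folds,
        seed=seed,
        n_genes=len(genes),
        scale=design_scale,
    )
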