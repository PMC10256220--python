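"""Gene filtering and cross-cohort renormalization.

The discovery cohort fixes everything: the top-k most variable genes are
chosen by median absolute deviation (MAD) on the training samples, and the
min-max renormalization that maps each training gene into [0, 1] stores the
training min/max so that external cohorts are rescaled against the *same*
anchors. External values may therefore fall outside [0, 1]; they are
deliberately not clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .types import ExpressionMatrix

__all__ = [
    "compute_mad",
    "select_top_variable_genes",
    "MinMaxReferenceScaler",
    "fit_minmax",
    "apply_minmax",
    "platform_concordance",
]


def compute_mad(values) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|).

    No consistency factor is applied; rankings are unaffected by scaling.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("compute_mad requires a non-empty vector")
    return float(np.median(np.abs(x - np.median(x))))


def select_top_variable_genes(expr: ExpressionMatrix, k: int) -> list:
    """Ids of the ``k`` genes with largest MAD across samples.

    Ties are broken by descending MAD then ascending gene id; the returned
    list preserves the original matrix order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.n_genes:
        raise ValueError(f"k={k} exceeds the {expr.n_genes} genes available")
    vals = expr.values
    mads = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    order = sorted(range(expr.n_genes), key=lambda i: (-mads[i], expr.gene_ids[i]))
    keep = sorted(order[:k])
    return [expr.gene_ids[i] for i in keep]


class MinMaxReferenceScaler(BaseEstimator, TransformerMixin):
    """Per-gene min-max scaler anchored to the training cohort.

    Follows the sklearn transformer protocol with samples as rows and genes
    as columns. ``transform`` maps training data into [0, 1] exactly; data
    from other cohorts may exceed that range and is not clipped.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        degenerate = np.flatnonzero(self.data_max_ <= self.data_min_)
        if degenerate.size:
            raise ValueError(
                "gene(s) with zero range on the training set at column(s) "
                f"{degenerate.tolist()}: min-max renormalization is undefined"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, ensure_min_samples=1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with the fitted scaler")
        return (X - self.data_min_) / (self.data_max_ - self.data_min_)


class NormalizationModel:
    """Per-gene training min/max, keyed and ordered by gene id."""

    def __init__(self, gene_ids: list, data_min: np.ndarray, data_max: np.ndarray):
        self.gene_ids = list(gene_ids)
        self.data_min = np.asarray(data_min, dtype=float)
        self.data_max = np.asarray(data_max, dtype=float)
        if (self.data_max < self.data_min).any():
            raise ValueError("max < min in normalization model")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "min": self.data_min, "max": self.data_max}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalizationModel":
        return cls(df["gene_id"].tolist(), df["min"].to_numpy(), df["max"].to_numpy())


def fit_minmax(expr_train: ExpressionMatrix) -> NormalizationModel:
    """Learn per-gene min/max over the training samples.

    Raises a degenerate-gene error naming the first offending gene if any
    gene has zero range.
    """
    if expr_train.scale_tag != "zscore":
        raise ValueError("fit_minmax expects z-score-scale input")
    if expr_train.n_samples < 2:
        raise ValueError("fit_minmax needs at least two samples")
    vals = expr_train.values
    mn, mx = vals.min(axis=1), vals.max(axis=1)
    degenerate = np.flatnonzero(mx <= mn)
    if degenerate.size:
        names = [expr_train.gene_ids[i] for i in degenerate[:5]]
        raise ValueError(f"degenerate gene(s) with zero range: {names}")
    return NormalizationModel(expr_train.gene_ids, mn, mx)


def apply_minmax(expr: ExpressionMatrix, model: NormalizationModel) -> ExpressionMatrix:
    """Rescale ``expr`` with the model's per-gene training min/max.

    Genes are taken in the model's order; a model gene missing from ``expr``
    raises a KeyError. Values outside [0, 1] are preserved unclipped.
    """
    missing = [g for g in model.gene_ids if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    sub = expr.data.loc[model.gene_ids]
    rng = model.data_max - model.data_min
    out = (sub.to_numpy(float) - model.data_min[:, None]) / rng[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=model.gene_ids, columns=expr.sample_ids),
        scale_tag="minmax",
    )


def platform_concordance(exprA: ExpressionMatrix, exprB: ExpressionMatrix):
    """Spearman rank correlation of per-gene means and of per-gene MADs
    between two cohorts, over their shared genes.

    Returns
    -------
    (srcc_of_means, srcc_of_mads) : tuple of float
    """
    shared = [g for g in exprA.gene_ids if g in set(exprB.gene_ids)]
    if len(shared) < 3:
        raise ValueError("platform concordance needs at least 3 shared genes")
    a = exprA.data.loc[shared].to_numpy(float)
    b = exprB.data.loc[shared].to_numpy(float)

    def gene_mads(x):
        return np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)

    srcc_means = spearmanr(a.mean(axis=1), b.mean(axis=1)).statistic
    srcc_mads = spearmanr(gene_mads(a), gene_mads(b)).statistic
    return float(srcc_means), float(srcc_mads)
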