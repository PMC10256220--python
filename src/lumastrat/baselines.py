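"""Comparison arms: K-means directly on expression or on PCA projections.

Every arm consumes the same samples and the same clustering hyperparameters
(k, seed, restarts) as the latent-feature arm, so the comparison isolates
the feature representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .autoencoder import LatentMatrix
from .stratify import kmeans_fit
from .survival import logrank_test
from .types import ExpressionMatrix, SurvivalTable

__all__ = ["BaselineResult", "pca_project", "run_baselines"]


@dataclass
class BaselineResult:
    feature_set: str
    k: int
    multivariate_p: float
    statistic: float


def pca_project(expr: ExpressionMatrix, n_components: int) -> pd.DataFrame:
    """Samples x components PCA scores (gene-wise mean centering, no
    variance scaling).

    Components are ordered by decreasing explained variance; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    n_max = min(expr.n_genes, expr.n_samples)
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must lie in [1, {n_max}]")
    X = expr.samples_by_genes()
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    out = pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


def _cluster_logrank(
    values: np.ndarray, sample_ids: list, survival: SurvivalTable, k: int, seed: int
):
    latent = LatentMatrix(sample_ids, values)
    labels, _ = kmeans_fit(latent, k, seed)
    groups = [survival.subset(labels == c) for c in range(k)]
    return logrank_test(groups)


def run_baselines(
    expr_full: ExpressionMatrix,
    expr_topk: ExpressionMatrix,
    latent: LatentMatrix,
    survival: SurvivalTable,
    k: int = 2,
    seed: int = 0,
    pca_dims=(64, 2),
) -> pd.DataFrame:
    """K-means(k) + multivariate log-rank for each feature set.

    Arms: full expression, top-variable expression, PCA projections of both
    at each width in ``pca_dims``, and the autoencoder latent features.
    Returns a DataFrame sorted by p-value.
    """
    sample_ids = expr_full.sample_ids
    if expr_topk.sample_ids != sample_ids or latent.sample_ids != sample_ids:
        raise KeyError("all baseline arms must share the same samples")
    if survival.sample_ids != sample_ids:
        raise KeyError("survival table samples do not match the expression arms")

    arms: dict[str, np.ndarray] = {
        "full": expr_full.samples_by_genes(),
        "topk": expr_topk.samples_by_genes(),
    }
    for d in pca_dims:
        arms[f"pca{d}_full"] = pca_project(expr_full, d).to_numpy()
        arms[f"pca{d}_topk"] = pca_project(expr_topk, d).to_numpy()
    arms["latent"] = latent.values

    rows = []
    for tag, values in arms.items():
        res = _cluster_logrank(values, sample_ids, survival, k, seed)
        rows.append(
            BaselineResult(
                feature_set=tag, k=k, multivariate_p=res.p, statistic=res.statistic
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "multivariate_p", kind="mergesort", ignore_index=True
    )
    return df
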