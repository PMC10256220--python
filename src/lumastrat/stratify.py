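"""Latent-space subgroup discovery and prognosis naming.

K-means (k = 2..5) partitions the per-sample latent features; the (dim, k)
stratification is selected by survival separation: a candidate is
admissible when *every* pairwise log-rank p-value is below alpha, and among
admissible candidates the one with the smallest multivariate log-rank p
wins. For k = 2 the cluster with the larger restricted mean survival time
is named BPS (better prognostic subgroup) and the other WPS; for k > 2
ordinal names P1..Pk are assigned by decreasing RMST. External samples are
assigned to the nearest centroid (Euclidean), ties resolved toward the
lower cluster index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans

from .autoencoder import LatentMatrix
from .survival import logrank_test, pairwise_logrank, rmst
from .types import SurvivalTable

__all__ = [
    "kmeans_fit",
    "LatentStratifier",
    "StratificationResult",
    "select_stratification",
    "assign_prognosis_labels",
    "assign_new_samples",
]

logger = logging.getLogger(__name__)


def kmeans_fit(latent: LatentMatrix, k: int, seed: int):
    """Lloyd's algorithm with k-means++ seeding and 10 restarts.

    Returns (labels, centroids); deterministic given ``seed``.
    """
    n = len(latent.sample_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples available")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(latent.values)
    return labels, km.cluster_centers_


def _split_by_cluster(survival: SurvivalTable, labels: np.ndarray, k: int):
    return [survival.subset(labels == c) for c in range(k)]


def assign_prognosis_labels(labels: np.ndarray, survival: SurvivalTable) -> dict:
    """Name clusters by prognosis using restricted mean survival time.

    The RMST horizon is the full follow-up window (the largest observed
    time over all clusters); beyond a cluster's own follow-up the KM
    estimate is carried forward. For two clusters the larger-RMST cluster
    is "BPS" and the other "WPS"; for k > 2, "P1" (best) .. "Pk" (worst).
    An RMST tie is broken toward the larger cluster and logged.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    groups = {c: survival.subset(labels == c) for c in clusters}
    horizon = max(g.time.max() for g in groups.values())
    if horizon <= 0:
        horizon = 1.0
    scores = {c: rmst(g, horizon) for c, g in groups.items()}
    sizes = {c: len(g) for c, g in groups.items()}
    if len(set(np.round(list(scores.values()), 12))) < len(clusters):
        logger.warning("RMST tie between clusters; breaking toward the larger cluster")
    order = sorted(clusters, key=lambda c: (-scores[c], -sizes[c], c))
    if len(clusters) == 2:
        return {order[0]: "BPS", order[1]: "WPS"}
    return {c: f"P{i + 1}" for i, c in enumerate(order)}


class LatentStratifier(BaseEstimator, ClassifierMixin):
    """Fitted stratification: centroids plus a cluster -> prognosis map.

    ``predict`` assigns each latent vector to the nearest centroid
    (Euclidean distance); equidistant samples go to the lower cluster index.
    """

    def __init__(self, hidden_dim: int = 64, k: int = 2, seed: int = 0):
        self.hidden_dim = hidden_dim
        self.k = k
        self.seed = seed

    def fit(self, latent: LatentMatrix, survival: SurvivalTable):
        if latent.dim != self.hidden_dim:
            raise ValueError("latent dim does not match hidden_dim")
        labels, centroids = kmeans_fit(latent, self.k, self.seed)
        self.centroids_ = centroids
        self.labels_ = labels
        self.prognosis_map_ = assign_prognosis_labels(labels, survival)
        groups = _split_by_cluster(survival, labels, self.k)
        multi = logrank_test(groups)
        pw = pairwise_logrank(groups)
        self.selection_record_ = {
            "multivariate_p": multi.p,
            "multivariate_statistic": multi.statistic,
            "pairwise_p": pw.to_numpy(),
        }
        return self

    def predict(self, latent: LatentMatrix) -> np.ndarray:
        if latent.dim != self.centroids_.shape[1]:
            raise ValueError(
                f"latent dim {latent.dim} does not match model dim "
                f"{self.centroids_.shape[1]}"
            )
        d = np.linalg.norm(
            latent.values[:, None, :] - self.centroids_[None, :, :], axis=2
        )
        return np.argmin(d, axis=1)  # argmin takes the lower index on ties

    def prognosis_labels(self, cluster_labels: np.ndarray) -> list:
        return [self.prognosis_map_[int(c)] for c in cluster_labels]

    def to_dict(self) -> dict:
        return {
            "hidden_dim": self.hidden_dim,
            "k": self.k,
            "seed": self.seed,
            "centroids": self.centroids_.tolist(),
            "prognosis_map": {str(c): p for c, p in self.prognosis_map_.items()},
            "multivariate_p": self.selection_record_["multivariate_p"],
            "pairwise_p": np.asarray(self.selection_record_["pairwise_p"]).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentStratifier":
        model = cls(hidden_dim=d["hidden_dim"], k=d["k"], seed=d.get("seed", 0))
        model.centroids_ = np.asarray(d["centroids"], dtype=float)
        model.prognosis_map_ = {int(c): p for c, p in d["prognosis_map"].items()}
        model.selection_record_ = {
            "multivariate_p": d["multivariate_p"],
            "pairwise_p": np.asarray(d["pairwise_p"], dtype=float),
        }
        return model


@dataclass
class StratificationResult:
    """Outcome of the (dim, k) model search.

    ``model`` is None when no candidate passed the pairwise admissibility
    screen (the explicit "no-stratification" outcome); ``candidates`` lists
    every (dim, k) examined with its test results.
    """

    model: LatentStratifier | None
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def stratified(self) -> bool:
        return self.model is not None


def select_stratification(
    latents: dict,
    survival: SurvivalTable,
    k_range=(2, 3, 4, 5),
    alpha_pairwise: float = 0.05,
    seed: int = 0,
) -> StratificationResult:
    """Search (hidden dim, k) for the most survival-separated stratification.

    Parameters
    ----------
    latents : dict mapping hidden dim -> LatentMatrix
        Latent features from the non-overfit autoencoder widths.
    alpha_pairwise : float
        Admissibility threshold: every pairwise log-rank p must fall below
        it (raw, unadjusted).
    """
    rows = []
    fitted = {}
    for dim in sorted(latents):
        latent = latents[dim]
        for k in k_range:
            model = LatentStratifier(hidden_dim=dim, k=k, seed=seed)
            model.fit(latent, survival)
            pw = np.asarray(model.selection_record_["pairwise_p"])
            off = pw[np.triu_indices(k, 1)]
            admissible = bool((off < alpha_pairwise).all())
            rows.append(
                {
                    "dim": dim,
                    "k": k,
                    "multivariate_p": model.selection_record_["multivariate_p"],
                    "max_pairwise_p": float(off.max()),
                    "admissible": admissible,
                }
            )
            fitted[(dim, k)] = model
    candidates = pd.DataFrame(rows)
    admissible = candidates[candidates["admissible"]]
    if admissible.empty:
        return StratificationResult(model=None, candidates=candidates)
    best = admissible.sort_values(
        ["multivariate_p", "dim", "k"], kind="mergesort"
    ).iloc[0]
    return StratificationResult(
        model=fitted[(int(best["dim"]), int(best["k"]))], candidates=candidates
    )


def assign_new_samples(latent_new: LatentMatrix, model: LatentStratifier) -> np.ndarray:
    """Nearest-centroid assignment of external samples (Euclidean)."""
    return model.predict(latent_new)
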