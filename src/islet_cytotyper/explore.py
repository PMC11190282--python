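"""Exploratory analysis of the single-cell feature matrix.

Dimensionality reduction (PCA with explained variance), a k-means elbow
scan over the within-cluster sum of squares

    WCSS(c_1..c_d) = (1/N) sum_i min_j || x_i - c_j ||^2 ,

per-cluster Gini impurity against the immunofluorescence-derived labels

    G(j) = 1 - sum_k (n_kj / n_j)^2 ,     G = (1/d) sum_j G(j) ,

and a two-cluster k-means ROC-AUC baseline that quantifies how much
cell-type signal unsupervised clustering alone can recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["Embedding", "ClusteringResult", "pca_embed", "wcss",
           "elbow_scan", "gini_report", "cluster_auc"]


@dataclass
class Embedding:
    coordinates: np.ndarray          # N x k
    explained_variance: np.ndarray   # fraction per component, non-increasing
    loadings: np.ndarray             # k x n_features


@dataclass
class ClusteringResult:
    assignments: np.ndarray
    centroids: np.ndarray
    wcss: float
    per_cluster_gini: list[float] = field(default_factory=list)
    mean_gini: float = float("nan")


def pca_embed(matrix: np.ndarray | pd.DataFrame, k: int = 2) -> Embedding:
    """Mean-centered PCA embedding with explained-variance fractions.

    Deterministic up to component sign; the sign is fixed by requiring the
    largest-magnitude loading of each component to be positive.
    """
    X = np.asarray(matrix, dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds the matrix rank bound {min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            coords[:, i] *= -1.0
    return Embedding(coordinates=coords,
                     explained_variance=pca.explained_variance_ratio_,
                     loadings=loadings)


def wcss(points: np.ndarray, assignments: np.ndarray,
         centroids: np.ndarray) -> float:
    """Mean squared distance of each point to its own cluster centroid.

    Normalized by the total number of points, so duplicating the data with
    unchanged centroids leaves the value unchanged.  An empty cluster
    contributes nothing (with a logged warning).
    """
    X = np.asarray(points, dtype=float)
    a = np.asarray(assignments)
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if a.shape[0] != X.shape[0]:
        raise ValueError("assignments must match the number of points")
    if a.min() < 0 or a.max() >= C.shape[0]:
        raise ValueError("assignment refers to a nonexistent centroid")
    present = np.unique(a)
    if present.size < C.shape[0]:
        logger.warning("wcss: %d empty cluster(s) contribute 0",
                       C.shape[0] - present.size)
    d2 = ((X - C[a]) ** 2).sum(axis=1)
    return float(d2.sum() / X.shape[0])


def _fit_kmeans(X: np.ndarray, k: int, seed: int,
                n_restarts: int = 10) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    km.fit(X)
    return km


def elbow_scan(points: np.ndarray, k_min: int = 2, k_max: int = 59,
               seed: int = 0, n_restarts: int = 10,
               ) -> tuple[pd.DataFrame, int, bool]:
    """Scan k-means over ``k_min..k_max`` and locate the WCSS elbow.

    The knee is the interior point of maximum discrete curvature of the
    WCSS curve on a log scale (second difference of log WCSS), i.e. the k
    at which the *relative* per-cluster improvement collapses; the log
    scale makes the rule invariant to the overall variance of the data.
    Returns ``(curve, knee_k, confident)`` where ``confident`` is False
    when the curvature peak is shallow (below 0.25 in log units, a smooth
    structureless decay) or barely dominates the rest of the curve.
    """
    X = np.asarray(points, dtype=float)
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be smaller than the number of points")
    ks = np.arange(k_min, k_max + 1)
    values = []
    for k in ks:
        km = _fit_kmeans(X, int(k), seed, n_restarts)
        values.append(wcss(X, km.labels_, km.cluster_centers_))
    values = np.asarray(values)
    curve = pd.DataFrame({"k": ks, "wcss": values})
    if ks.size < 3:
        return curve, int(ks[np.argmin(values)]), False
    logv = np.log(np.maximum(values, 1e-300))
    curvature = logv[:-2] - 2 * logv[1:-1] + logv[2:]
    knee_idx = int(np.argmax(curvature)) + 1
    knee = int(ks[knee_idx])
    peak = float(curvature[knee_idx - 1])
    others = np.delete(curvature, knee_idx - 1)
    spread = float(np.abs(others).max()) if others.size else 0.0
    confident = bool(peak > 0.25 and peak > 1.2 * spread)
    if not confident:
        logger.warning("elbow_scan: low-confidence knee at k=%d", knee)
    return curve, knee, confident


def gini_report(assignments: np.ndarray, labels: np.ndarray | pd.Series,
                ) -> tuple[dict[int, float], float]:
    """Per-cluster Gini impurity and its unweighted average over clusters.

    ``G(j) = 1 - sum_k (n_kj / n_j)^2`` over the classes present in the
    labels; a pure cluster scores 0, a 50/50 two-class cluster 0.5.  The
    average is over clusters (not size-weighted).  Empty clusters are
    excluded from the average with a warning.
    """
    a = np.asarray(assignments)
    y = np.asarray(labels)
    if a.shape[0] != y.shape[0]:
        raise ValueError("labels must be available for every point")
    per_cluster: dict[int, float] = {}
    for j in np.unique(a):
        yj = y[a == j]
        if yj.size == 0:  # unreachable via np.unique, kept for direct calls
            logger.warning("gini_report: cluster %d is empty, excluded", j)
            continue
        _, counts = np.unique(yj, return_counts=True)
        p = counts / yj.size
        per_cluster[int(j)] = float(1.0 - (p ** 2).sum())
    mean_gini = float(np.mean(list(per_cluster.values())))
    return per_cluster, mean_gini


def cluster_auc(embedding: np.ndarray, labels: np.ndarray | pd.Series,
                k: int = 2, seed: int = 0,
                positive_label: str | int = "beta") -> float:
    """ROC-AUC of a k-cluster k-means used as an unsupervised classifier.

    Each point is scored by the fraction of positive-class members in its
    cluster, making the AUC invariant to cluster relabelling.  A degenerate
    single-cluster outcome scores 0.5 (chance) with a warning.
    """
    X = np.asarray(embedding, dtype=float)
    y = (np.asarray(labels) == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    km = _fit_kmeans(X, k, seed)
    a = km.labels_
    if np.unique(a).size < 2:
        logger.warning("cluster_auc: degenerate single-cluster outcome")
        return 0.5
    score = np.empty(X.shape[0])
    for j in np.unique(a):
        score[a == j] = y[a == j].mean()
    if np.unique(score).size == 1:
        logger.warning("cluster_auc: constant score, returning chance level")
        return 0.5
    return float(roc_auc_score(y, score))
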