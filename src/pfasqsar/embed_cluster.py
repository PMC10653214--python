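"""Dimension reduction, k-means clustering, and silhouette-based model selection.

PCA feeds a 2-D t-SNE map for visualization; clustering runs on the PCA
space by default (a flag in the pipeline switches to the 2-D t-SNE space).
k-means is Lloyd's algorithm with k-means++ seeding and multiple restarts,
implemented here directly so the per-iteration inertia trace is observable.
The silhouette score of a partition is the model-selection criterion: the
candidate k with the best silhouette wins, ties broken toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA as _SkPCA
from sklearn.manifold import TSNE as _SkTSNE
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import DimensionError, ParameterError

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "pca",
    "tsne",
    "kmeans",
    "silhouette",
    "select_k",
]


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Project scores back to the original space (adds the mean back)."""
        return self.scores @ self.components + self.mean


@dataclass
class ClusterAssignment:
    """A k-means partition with its silhouette score.

    Every cluster index in 0..k-1 is non-empty; the silhouette is
    recomputable from (points, labels).
    """

    labels: np.ndarray
    k: int
    silhouette: float
    seed: int
    inertia: float
    inertia_trace: list[float] = field(default_factory=list)
    centers: np.ndarray | None = None


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal component scores plus explained-variance ratios.

    ``n_components`` must not exceed min(rows - 1, cols).
    """
    X = np.asarray(X, dtype=np.float64)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise DimensionError(
            f"n_components must lie in [1, {limit}] for shape {X.shape}, "
            f"got {n_components}"
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        components=model.components_,
        mean=model.mean_,
    )


def tsne(X: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding, deterministic under a fixed seed.

    Requires rows > 3 * perplexity.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] <= 3 * perplexity:
        raise ParameterError(
            f"t-SNE needs rows > 3 * perplexity; got {X.shape[0]} rows for "
            f"perplexity {perplexity}"
        )
    model = _SkTSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return model.fit_transform(X)


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=np.int64)
    inertia = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(X.shape[0]), labels].sum())
        trace.append(inertia)
        new_centers = centers.copy()
        for c in range(k):
            members = labels == c
            if members.any():
                new_centers[c] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its center
                far = d2[np.arange(X.shape[0]), labels].argmax()
                new_centers[c] = X[far]
        shift = float(np.linalg.norm(new_centers - centers))
        centers = new_centers
        if shift <= tol:
            break
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    final = float(d2[np.arange(X.shape[0]), labels].sum())
    if not trace or final < trace[-1]:
        trace.append(final)
    return labels, centers, trace[-1], trace


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> ClusterAssignment:
    """k-means++ / Lloyd clustering, best of ``n_init`` restarts by inertia."""
    X = np.asarray(X, dtype=np.float64)
    if not 2 <= k <= X.shape[0]:
        raise ParameterError(f"k must lie in [2, {X.shape[0]}], got {k}")
    if n_init < 1:
        raise ParameterError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_init):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=restart_seed)
        labels, centers, inertia, trace = _lloyd(X, centers, max_iter, tol)
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers, trace)
    assert best is not None
    inertia, labels, centers, trace = best
    if len(np.unique(labels)) < 2:
        raise ParameterError("k-means collapsed to a single cluster")
    score = silhouette(X, labels)
    return ClusterAssignment(
        labels=labels,
        k=k,
        silhouette=score,
        seed=seed,
        inertia=inertia,
        inertia_trace=trace,
        centers=centers,
    )


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score, Euclidean metric.

    Per point: (b - a) / max(a, b) with a the mean intra-cluster distance and
    b the smallest mean distance to another cluster.  Requires at least two
    non-empty clusters.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("silhouette is undefined for a single cluster")
    return float(_sk_silhouette(X, labels, metric="euclidean"))


def select_k(
    X: np.ndarray,
    k_candidates: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Run k-means for each candidate and keep the best-silhouette partition.

    Candidates are evaluated in ascending order with a strict improvement
    rule, so ties resolve toward the smaller k.
    """
    if not k_candidates:
        raise ParameterError("k_candidates must be non-empty")
    best: ClusterAssignment | None = None
    for k in sorted(set(int(k) for k in k_candidates)):
        assignment = kmeans(X, k=k, seed=seed, n_init=n_init)
        if best is None or assignment.silhouette > best.silhouette:
            best = assignment
    assert best is not None
    return best
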