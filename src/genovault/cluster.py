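"""K-means with model-selection diagnostics: clustergram, silhouette, best-k.

The k-means here is a self-contained implementation — k-means++ seeding,
Lloyd iterations to an inertia tolerance of 1e-8 (300 iteration cap), best
of ``n_init`` restarts — so that fixed-seed byte reproducibility is a hard
contract of this package rather than a property borrowed from another
library's internals.

The clustergram tracks, across a range of k, each cluster's centroid
projected onto the first principal component of the data (its vertical
position), its cardinality (point size), and how observations flow between
clusters of consecutive k fits (edge weights).  Silhouette analysis then
scores each k; ``suggest_k`` picks the k with the highest mean coefficient,
breaking ties toward the smaller (simpler) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist


class ClusterError(Exception):
    pass


@dataclass
class KmeansModel:
    k: int
    labels: np.ndarray       # per-observation cluster index in [0, k)
    centers: np.ndarray      # k × features
    inertia: float
    seed: int
    n_init: int
    n_iter: int

    def __post_init__(self):
        sizes = np.bincount(self.labels, minlength=self.k)
        if (sizes == 0).any():
            raise ClusterError("fitted model has an empty cluster")


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all points coincide with a center
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int]:
    n, k = X.shape[0], centers.shape[0]
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)  # ties -> lowest cluster index
        # re-seat empty clusters on the worst-fit points
        sizes = np.bincount(labels, minlength=k)
        for empty in np.flatnonzero(sizes == 0):
            far = int(d2[np.arange(n), labels].argmax())
            labels[far] = empty
            d2[far, :] = np.inf
            d2[far, empty] = 0.0
        inertia = 0.0
        for j in range(k):
            pts = X[labels == j]
            centers[j] = pts.mean(axis=0)
            inertia += float(((pts - centers[j]) ** 2).sum())
        if abs(prev_inertia - inertia) <= tol * max(1.0, abs(prev_inertia)):
            return labels, centers, inertia, it
        prev_inertia = inertia
    return labels, centers, prev_inertia, max_iter


def kmeans(
    X: np.ndarray | Sequence[Sequence[float]],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> KmeansModel:
    """Fit k-means: k-means++ init, Lloyd updates, best of ``n_init`` restarts.

    Deterministic for a given seed; the restart with the lowest inertia
    wins (first such restart on exact ties).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ClusterError("X must be observations × features")
    n = X.shape[0]
    if k <= 0:
        raise ClusterError(f"k must be positive, got {k}")
    if k > n:
        raise ClusterError(f"k={k} exceeds n={n} observations")
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6B6D]))
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(n_init):
        centers0 = _kmeanspp(X, k, root)
        labels, centers, inertia, n_iter = _lloyd(
            X, centers0.copy(), max_iter, tol
        )
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers, n_iter)
    inertia, labels, centers, n_iter = best
    return KmeansModel(
        k=k,
        labels=labels,
        centers=centers,
        inertia=inertia,
        seed=int(seed),
        n_init=n_init,
        n_iter=n_iter,
    )


@dataclass
class SilhouetteResult:
    coefficients: np.ndarray          # per observation, in [-1, 1]
    cluster_means: dict[int, float]
    overall_mean: float


def silhouette(
    X: np.ndarray | Sequence[Sequence[float]], labels: Sequence[int]
) -> SilhouetteResult:
    """Silhouette coefficients s(i) = (b_i − a_i) / max(a_i, b_i).

    a_i: mean distance to the other members of i's own cluster; b_i: the
    smallest mean distance to any other cluster.  A member of a singleton
    cluster scores 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ClusterError("silhouette needs at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    sizes = {int(c): int((labels == c).sum()) for c in clusters}
    for i in range(n):
        own = int(labels[i])
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        mask_own = labels == own
        a = D[i, mask_own].sum() / (sizes[own] - 1)  # excludes self (D[i,i]=0)
        b = min(
            D[i, labels == c].mean() for c in clusters if c != own
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    cluster_means = {
        int(c): float(s[labels == c].mean()) for c in clusters
    }
    return SilhouetteResult(
        coefficients=s,
        cluster_means=cluster_means,
        overall_mean=float(s.mean()),
    )


@dataclass
class ClustergramModel:
    k_range: list[int]
    # (k, cluster) -> {"position": PC1 projection of centroid, "size": count}
    nodes: dict[tuple[int, int], dict] = dc_field(default_factory=dict)
    # (k, cluster_at_k, cluster_at_next_k) -> observation count
    edges: dict[tuple[int, int, int], int] = dc_field(default_factory=dict)
    models: dict[int, KmeansModel] = dc_field(default_factory=dict)


def _pc1_axis(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal axis of X and the data mean (for projecting centroids)."""
    mean = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - mean, full_matrices=False)
    axis = Vt[0]
    i = int(np.argmax(np.abs(axis)))
    if axis[i] < 0:
        axis = -axis
    return axis, mean


def clustergram(
    X: np.ndarray | Sequence[Sequence[float]],
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
) -> ClustergramModel:
    """Cluster stability diagram across k.

    Node position: cluster centroid projected onto PC1 of the (centered)
    data; node size: cluster cardinality; edges: counts of observations
    moving between clusters of consecutive k fits.
    """
    X = np.asarray(X, dtype=float)
    ks = list(k_range)
    if not ks:
        raise ClusterError("empty k_range")
    if max(ks) > X.shape[0]:
        raise ClusterError(f"max k {max(ks)} exceeds n={X.shape[0]}")
    axis, mean = _pc1_axis(X)
    model = ClustergramModel(k_range=ks)
    for k in ks:
        fit = kmeans(X, k, seed=seed, n_init=n_init)
        model.models[k] = fit
        sizes = np.bincount(fit.labels, minlength=k)
        for c in range(k):
            model.nodes[(k, c)] = {
                "position": float((fit.centers[c] - mean) @ axis),
                "size": int(sizes[c]),
            }
    for k, k_next in zip(ks, ks[1:]):
        a = model.models[k].labels
        b = model.models[k_next].labels
        for ca, cb in zip(a, b):
            key = (k, int(ca), int(cb))
            model.edges[key] = model.edges.get(key, 0) + 1
    return model


def suggest_k(
    X: np.ndarray | Sequence[Sequence[float]],
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
) -> dict:
    """Pick k by mean silhouette over ``k_range`` (ties -> smaller k).

    Returns {"k_best", "scores": {k: mean silhouette}, "models": {k: fit}}.
    """
    X = np.asarray(X, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ClusterError(
            f"k_range must lie within [2, n-1]=[2, {X.shape[0] - 1}], got {ks}"
        )
    scores: dict[int, float] = {}
    models: dict[int, KmeansModel] = {}
    for k in ks:
        fit = kmeans(X, k, seed=seed, n_init=n_init)
        models[k] = fit
        scores[k] = silhouette(X, fit.labels).overall_mean
    k_best = max(ks, key=lambda k: (scores[k], -k))
    return {"k_best": k_best, "scores": scores, "models": models}
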