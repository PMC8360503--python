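"""Representational geometry: sliding-window nonmetric MDS and k-means.

Neural RDM time series are averaged within an 80-ms sliding window (20-ms
step), each windowed RDM is embedded in two dimensions by nonmetric MDS
(Kruskal stress-1, best of 10 random initial configurations), and the
embedding is partitioned by k-means (squared Euclidean distortion) with the
mean silhouette value as the cluster-validity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .mvpa import RDMSeries, PAIRS

__all__ = [
    "EmbeddingResult",
    "ClusterSolution",
    "sliding_window_rdms",
    "nonmetric_mds",
    "kmeans_cluster",
    "silhouette_curve",
    "kruskal_stress",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Nonmetric MDS embedding of one windowed RDM."""

    window_center_ms: float
    coordinates: np.ndarray  # (10, n_dims), defined up to similarity transform
    stress: float  # Kruskal stress-1 in [0, 1]
    n_dims: int
    n_inits: int


@dataclass(frozen=True)
class ClusterSolution:
    """k-means partition of an embedding with its mean silhouette value."""

    k: int
    assignments: np.ndarray
    mean_silhouette: float

    def __post_init__(self):
        if not (-1.0 <= self.mean_silhouette <= 1.0):
            raise ValueError("mean silhouette must lie in [-1, 1]")


def sliding_window_rdms(
    rdm: RDMSeries,
    window_ms: float = 80.0,
    step_ms: float = 20.0,
) -> List[Tuple[float, np.ndarray]]:
    """Time-average the 45-pair series within sliding windows.

    Windows lie fully inside the epoch; each output is (center in ms,
    window-mean 45-vector).
    """
    times = rdm.times
    dt = float(times[1] - times[0])
    w = int(round(window_ms / dt))
    hop = max(int(round(step_ms / dt)), 1)
    if w > len(times):
        raise ValueError(f"window of {window_ms} ms exceeds the epoch length")
    w = max(w, 1)
    out = []
    for start in range(0, len(times) - w + 1, hop):
        stop = start + w
        center = float(times[start:stop].mean())
        out.append((center, rdm.values[start:stop].mean(axis=0)))
    return out


def kruskal_stress(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against the input dissimilarities.

    Disparities are the monotone (isotonic) regression of the embedding
    distances on the dissimilarity order; stress-1 =
    sqrt(sum (d - dhat)^2 / sum d^2).
    """
    d = pdist(coordinates)
    delta = np.asarray(dissimilarities, dtype=float)
    iso = IsotonicRegression(increasing=True)
    dhat = iso.fit_transform(delta, d)
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _as_square(dissimilarities: np.ndarray) -> np.ndarray:
    v = np.asarray(dissimilarities, dtype=float)
    if v.ndim == 1:
        return squareform(v)
    return v


def nonmetric_mds(
    dissimilarities: np.ndarray,
    n_dims: int = 2,
    n_inits: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> EmbeddingResult:
    """Nonmetric MDS of a 45-vector (or square matrix) of dissimilarities.

    Monotone-regression-based scaling minimizing Kruskal stress-1; the best
    of ``n_inits`` random initial configurations is returned.  Reproducible
    from ``seed``.
    """
    square = _as_square(dissimilarities)
    if np.any(square < 0):
        raise ValueError("dissimilarities must be non-negative")
    if np.all(square == 0):
        raise ValueError("all dissimilarities are zero; the embedding is undefined")
    try:  # sklearn >= 1.9 parameter names
        mds = MDS(
            n_components=n_dims,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=n_inits,
            random_state=seed,
            max_iter=max_iter,
            eps=1e-6,
            normalized_stress=True,
        )
    except TypeError:  # older sklearn
        mds = MDS(
            n_components=n_dims,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_inits,
            random_state=seed,
            max_iter=max_iter,
            eps=1e-6,
            normalized_stress=True,
        )
    coords = mds.fit_transform(square)
    vec = squareform(square)
    return EmbeddingResult(
        window_center_ms=np.nan,
        coordinates=coords,
        stress=kruskal_stress(vec, coords),
        n_dims=n_dims,
        n_inits=n_inits,
    )


def kmeans_cluster(
    embedding: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterSolution:
    """k-means on embedding coordinates (squared Euclidean distortion).

    Multiple restarts are run and the lowest-distortion solution kept; the
    mean silhouette value is computed on the same embedding.
    """
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must be in [2, {n - 1}] for {n} points, got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    sil = float(silhouette_score(x, labels))
    return ClusterSolution(k=k, assignments=labels, mean_silhouette=sil)


def align_cluster_ids(solution: ClusterSolution, anchor: int = 0) -> np.ndarray:
    """Relabel clusters so the cluster containing the anchor stimulus is 0."""
    labels = solution.assignments.copy()
    a = labels[anchor]
    labels = np.where(labels == a, -1, labels)
    # compact remaining ids deterministically by first appearance
    next_id = 1
    mapping = {-1: 0}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = next_id
            next_id += 1
        out[i] = mapping[l]
    return out


def silhouette_curve(
    rdm: RDMSeries,
    k_values: Sequence[int] = (2, 3, 4, 5),
    window_ms: float = 80.0,
    step_ms: float = 20.0,
    n_dims: int = 2,
    n_inits: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean silhouette per sliding window and cluster count.

    Composition of sliding-window averaging, nonmetric MDS and k-means;
    returns a tidy frame with columns window_center_ms, k, silhouette,
    stress, task, subset.
    """
    rows = []
    for wi, (center, vec) in enumerate(sliding_window_rdms(rdm, window_ms, step_ms)):
        emb = nonmetric_mds(vec, n_dims=n_dims, n_inits=n_inits, seed=seed + wi)
        for k in k_values:
            sol = kmeans_cluster(emb.coordinates, k, seed=seed + wi)
            rows.append(
                {
                    "task": rdm.task,
                    "subset": rdm.sensor_subset,
                    "window_center_ms": center,
                    "k": k,
                    "silhouette": sol.mean_silhouette,
                    "stress": emb.stress,
                }
            )
    return pd.DataFrame(rows)
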