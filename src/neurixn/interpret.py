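"""Interpretation of learned spatial filters: sign alignment, two-level
clustering (cosine k-means per participant, hierarchical across
participants), and z-score significance thresholding of interaction weights.

A spatial filter is a 45-vector over region pairs; ``v`` and ``-v`` describe
the same filter up to a sign absorbed downstream, so all cosine-distance
computations operate on sign-aligned vectors (largest-magnitude entry made
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy
import scipy.stats
from sklearn.metrics import silhouette_score

from .data_model import PairIndex


class DegenerateFilterError(ValueError):
    """A filter is all-zero or constant and cannot be analysed."""


@dataclass
class ClusterResult:
    level: str  # {"individual", "group"}
    centroids: np.ndarray  # (k, 45)
    assignments: np.ndarray  # (n,)
    inertia: float
    silhouette: float = float("nan")
    linkage: np.ndarray | None = None


@dataclass
class SignificantInteractionSet:
    """Pair indices of a filter whose weights deviate from the filter's own
    mean by a two-sided normal test at ``p_threshold``."""

    filter_id: int
    indices: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    p_threshold: float = 0.05


def align_filter_signs(filters: np.ndarray) -> np.ndarray:
    """Multiply each row by +/-1 so its largest-magnitude entry is positive."""
    filters = np.asarray(filters, dtype=np.float64)
    single = filters.ndim == 1
    F = np.atleast_2d(filters).copy()
    norms = np.linalg.norm(F, axis=1)
    if np.any(norms == 0):
        raise DegenerateFilterError("all-zero filter row cannot be sign-aligned")
    k = np.argmax(np.abs(F), axis=1)
    signs = np.sign(F[np.arange(len(F)), k])
    F *= signs[:, None]
    return F[0] if single else F


def _cosine_dist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    return 1.0 - Xn @ Cn.T


def kmeans_cosine(
    filters: np.ndarray,
    k: int = 4,
    restarts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """k-means under cosine distance (spherical k-means).

    Run ``restarts`` times from random centroid seeds, up to ``max_iter``
    Lloyd iterations each; the solution with the smallest within-cluster sum
    of cosine distances is kept.  Empty clusters are reseeded from the point
    farthest from its centroid.
    """
    X = np.asarray(filters, dtype=np.float64)
    n = len(X)
    if n < k:
        raise ValueError(f"{n} filters cannot form {k} clusters")
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _r in range(restarts):
        C = Xn[rng.choice(n, size=k, replace=False)].copy()
        assign = np.full(n, -1)
        for _it in range(max_iter):
            D = 1.0 - Xn @ C.T
            new_assign = D.argmin(axis=1)
            for j in range(k):
                if not np.any(new_assign == j):  # reseed empty cluster
                    worst = int(np.argmax(D[np.arange(n), new_assign]))
                    new_assign[worst] = j
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                m = Xn[assign == j].mean(axis=0)
                nm = np.linalg.norm(m)
                C[j] = m / nm if nm > 0 else Xn[rng.integers(n)]
        D = 1.0 - Xn @ C.T
        inertia = float(D[np.arange(n), assign].sum())
        if best is None or inertia < best[0]:
            best = (inertia, assign.copy(), C.copy())
    inertia, assign, C = best
    sil = float("nan")
    if 2 <= k <= n - 1 and len(set(assign.tolist())) > 1:
        sil = float(silhouette_score(X, assign, metric="cosine"))
    return ClusterResult(
        level="individual", centroids=C, assignments=assign, inertia=inertia, silhouette=sil
    )


def hierarchical_group_clusters(
    centroids: np.ndarray, n_clusters: int, linkage_method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of per-participant centroids.

    Average linkage on cosine distances; flat clusters cut at the requested
    count (3 for the within-participant study, 4 for cross-participant).
    Group centroids are the sign-aligned means of their members.
    """
    X = np.asarray(centroids, dtype=np.float64)
    if len(X) < n_clusters:
        raise ValueError(f"{len(X)} centroids cannot form {n_clusters} clusters")
    if n_clusters == len(X):
        assign = np.arange(len(X))
        Z = None
    else:
        Z = scipy.cluster.hierarchy.linkage(X, method=linkage_method, metric="cosine")
        assign = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    group_centroids = np.stack(
        [align_filter_signs(X[assign == j].mean(axis=0)) for j in range(assign.max() + 1)]
    )
    D = _cosine_dist(X, group_centroids)
    inertia = float(D[np.arange(len(X)), assign].sum())
    sil = float("nan")
    if 1 < n_clusters < len(X):
        sil = float(silhouette_score(X, assign, metric="cosine"))
    return ClusterResult(
        level="group",
        centroids=group_centroids,
        assignments=np.asarray(assign),
        inertia=inertia,
        silhouette=sil,
        linkage=Z,
    )


def significant_interactions(
    filter_vec: np.ndarray, p_threshold: float = 0.05, filter_id: int = -1
) -> SignificantInteractionSet:
    """Interaction weights that stand out within their own filter.

    Each weight is z-transformed against the filter's mean and standard
    deviation; two-sided p-values from the normal CDF, and indices with
    ``p < p_threshold`` (uncorrected) are retained.  Negative weights can be
    significant: the decoder can exploit suppressed interactions as well as
    enhanced ones.
    """
    w = np.asarray(filter_vec, dtype=np.float64)
    sd = w.std()
    if sd == 0:
        raise DegenerateFilterError("constant filter has no significant structure")
    z = (w - w.mean()) / sd
    p = 2.0 * (1.0 - scipy.stats.norm.cdf(np.abs(z)))
    idx = np.flatnonzero(p < p_threshold)
    return SignificantInteractionSet(
        filter_id=filter_id, indices=idx, z_values=z, p_values=p, p_threshold=p_threshold
    )


def elbow_silhouette_scan(filters: np.ndarray, k_range, seed: int = 0):
    """Per-k inertia and mean cosine silhouette for choosing cluster counts."""
    import pandas as pd

    rows = []
    n = len(filters)
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, {n - 1}]")
        res = kmeans_cosine(filters, k=k, seed=seed)
        rows.append({"k": k, "inertia": res.inertia, "silhouette": res.silhouette})
    return pd.DataFrame(rows)


def plot_filter_heatmap(filter_vec: np.ndarray, pair_index: PairIndex, ax=None):
    """Render a 45-vector on the symmetric 10 x 10 region-pair grid."""
    import matplotlib.pyplot as plt

    codes: list[str] = []
    for a, b in pair_index.pairs:
        if a not in codes:
            codes.append(a)
        if b not in codes:
            codes.append(b)
    M = np.zeros((len(codes), len(codes)))
    for k, (a, b) in enumerate(pair_index.pairs):
        i, j = codes.index(a), codes.index(b)
        M[i, j] = M[j, i] = filter_vec[k]
    if ax is None:
        _fig, ax = plt.subplots()
    lim = np.abs(M).max() or 1.0
    im = ax.imshow(M, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(codes)), codes, rotation=90)
    ax.set_yticks(range(len(codes)), codes)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
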