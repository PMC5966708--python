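"""Per-task K-means clustering with silhouette-based choice of cluster count.

Participants are clustered per task on the three physiological features.
Because pupil dilation (tens of percent) and normalized GSR (~0.004) live
three orders of magnitude apart, features are standardized to zero mean
and unit variance before clustering by default; reported cluster centres
are mapped back to original units.  Candidate cluster counts (2, 3 and 4
by default) are compared by mean silhouette coefficient and ties go to
the smallest count.  For display, silhouette values are also expressed on
a 0-100% scale via the affine map ``50 * (s + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tasks import FEATURE_NAMES

__all__ = [
    "ClusterSolution",
    "standardize",
    "kmeans_fit",
    "kmeans",
    "silhouette_mean",
    "silhouette_percentage",
    "select_k",
    "cluster_all_tasks",
    "adjusted_rand_index",
]


@dataclass
class ClusterSolution:
    """One fitted clustering of one task's participants."""

    task_id: Optional[str]
    k: int
    assignments: np.ndarray
    centers: np.ndarray          # original feature units, shape (k, p)
    inertia: float               # sum of squared scaled distances
    silhouette: float
    silhouette_pct: float
    scaling_params: Tuple[np.ndarray, np.ndarray]  # (location, scale)

    @property
    def centers_scaled(self) -> np.ndarray:
        loc, scale = self.scaling_params
        return (self.centers - loc) / scale


def standardize(X: np.ndarray) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """Center each column to mean 0 and scale to sd 1.

    Constant columns are left at scale 1 (a warning is emitted) so they
    map to all-zeros rather than NaN.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    const = scale == 0
    if const.any():
        warnings.warn(
            f"constant feature column(s) {np.where(const)[0].tolist()}; "
            "left unscaled", stacklevel=2)
        scale = np.where(const, 1.0, scale)
    return (X - loc) / scale, (loc, scale)


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-centre assignment; empty clusters are repaired by turning
    the point farthest from its centre (from a cluster of size >= 2) into
    a singleton."""
    k = centers.shape[0]
    n = len(X)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    for j in range(k):
        if np.any(labels == j):
            continue
        own = d2[np.arange(n), labels].copy()
        sizes = np.bincount(labels, minlength=k)
        own[sizes[labels] < 2] = -np.inf
        far = int(own.argmax())
        labels[far] = j
        d2[far] = 0.0  # treat as sitting on its new centre
    return labels


def _lloyd(X: np.ndarray, centers: np.ndarray,
           max_iter: int) -> Tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    labels = _assign(X, centers)
    for _ in range(max_iter):
        new_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        new_labels = _assign(X, new_centers)
        done = np.array_equal(new_labels, labels)
        labels, centers = new_labels, new_centers
        if done:
            break
    centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    inertia = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def kmeans_fit(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
               max_iter: int = 300) -> Tuple[np.ndarray, np.ndarray, float]:
    """K-means on a prepared matrix: k-means++ seeding, Lloyd iterations,
    best of ``n_init`` restarts by inertia.  Returns (labels, centers,
    inertia)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers0 = _kmeans_pp_init(X, k, rng)
        labels, centers, inertia = _lloyd(X, centers0, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    return best


def silhouette_mean(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient ``(b - a) / max(a, b)`` with Euclidean
    distances.  Points in singleton clusters, and points at zero distance
    from both their own and the nearest other cluster, contribute 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = X.shape[0]
    dist = np.sqrt(np.maximum(
        ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2), 0.0))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        size_own = own.sum()
        if size_own <= 1:
            continue  # singleton contributes 0
        a = dist[i, own].sum() / (size_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def silhouette_percentage(s: float) -> float:
    """Affine display map from the silhouette scale [-1, 1] to 0-100%."""
    if not -1 <= s <= 1:
        raise ValueError(f"silhouette {s} outside [-1, 1]")
    return 50.0 * (s + 1.0)


def kmeans(task_features, k: int, seed: int = 0, *, task_id: Optional[str] = None,
           n_init: int = 10, max_iter: int = 300,
           scale: bool = True) -> ClusterSolution:
    """Cluster one task's feature matrix and package the full solution.

    ``task_features`` is an (n, p) array or a DataFrame containing the
    feature columns.  Standardization (on by default) is recorded in
    ``scaling_params``; centres are reported in original units.
    """
    X = _as_matrix(task_features)
    if scale:
        Xs, params = standardize(X)
    else:
        Xs, params = X.copy(), (np.zeros(X.shape[1]), np.ones(X.shape[1]))
    labels, centers_s, inertia = kmeans_fit(Xs, k, seed=seed, n_init=n_init,
                                            max_iter=max_iter)
    # stable output order: cluster with the larger first-feature centre
    # (pupil dilation) comes first
    order = np.argsort(-centers_s[:, 0], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers_s = centers_s[order]
    sil = silhouette_mean(Xs, labels) if k >= 2 else float("nan")
    loc, sc = params
    return ClusterSolution(
        task_id=task_id, k=k, assignments=labels,
        centers=centers_s * sc + loc, inertia=inertia,
        silhouette=sil,
        silhouette_pct=silhouette_percentage(sil) if k >= 2 else float("nan"),
        scaling_params=(loc, sc),
    )


def select_k(task_features, candidates: Sequence[int] = (2, 3, 4),
             seed: int = 0, *, task_id: Optional[str] = None,
             scale: bool = True,
             n_init: int = 10) -> Tuple[ClusterSolution, Dict[int, ClusterSolution]]:
    """Fit every candidate cluster count and keep the best mean silhouette.

    Ties are broken toward the smallest count.  Returns the chosen
    solution and the full candidate dict.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    fits: Dict[int, ClusterSolution] = {}
    for k in sorted(candidates):
        fits[k] = kmeans(task_features, k, seed=seed, task_id=task_id,
                         scale=scale, n_init=n_init)
    best_k = max(sorted(fits), key=lambda k: (fits[k].silhouette, -k))
    return fits[best_k], fits


def cluster_all_tasks(feature_table: pd.DataFrame, k: int = 2, seed: int = 0,
                      scale: bool = True) -> Dict[str, ClusterSolution]:
    """Fixed-k clustering of every task in a long-format feature table."""
    out: Dict[str, ClusterSolution] = {}
    for tid, grp in feature_table.groupby("task", sort=False):
        grp = grp.sort_values("participant")
        sol = kmeans(grp[list(FEATURE_NAMES)], k, seed=seed, task_id=tid,
                     scale=scale)
        out[tid] = sol
    return out


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (pair-counting
    form from the contingency table); 1 for identical partitions, ~0 for
    independent ones."""
    a = pd.Series(np.asarray(labels_a))
    b = pd.Series(np.asarray(labels_b))
    if len(a) != len(b):
        raise ValueError("partitions must have equal length")
    ct = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _as_matrix(task_features) -> np.ndarray:
    if isinstance(task_features, pd.DataFrame):
        cols = [c for c in FEATURE_NAMES if c in task_features.columns]
        if cols:
            return task_features[cols].to_numpy(dtype=float)
        return task_features.to_numpy(dtype=float)
    return np.asarray(task_features, dtype=float)
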