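"""Clustering of epigenetic features and AS types from the signed log-p
matrix, plus a classical MDS embedding.

Features are clustered with k-means (k = 4 by default) on their signed
log-p row vectors under Euclidean geometry; AS event types are clustered
with k = 2, which on real-like association structure separates the
exon-skipping-related process (ESRP: ES, ME) from the alternative
splice-site-selection process (ASSP: A3SS, A5SS, IR). Missing matrix
cells are imputed to 0 (no evidence in either direction) before
clustering. Cluster labels are canonicalised by sorting clusters on
their centroid's first principal coordinate, so reruns with the same
seed are label-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "kmeans_cluster", "cluster_as_types", "classical_mds"]

DEFAULT_RESTARTS = 25


@dataclass
class ClusterAssignment:
    items: list[str]
    labels: np.ndarray
    k: int
    seed: int
    wcss: float

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {int(l): [] for l in sorted(set(self.labels))}
        for item, l in zip(self.items, self.labels):
            out[int(l)].append(item)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": self.items, "label": self.labels, "k": self.k,
             "seed": self.seed, "wcss": self.wcss}
        )


def _impute(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.isna().any().any():
        logger.info("imputing %d missing matrix cells to 0", int(matrix.isna().sum().sum()))
        matrix = matrix.fillna(0.0)
    return matrix


def _canonical_labels(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters by centroid position along the data's first
    principal axis (ties broken by centroid norm)."""
    centroids = np.zeros((k, X.shape[1]))
    empty = np.zeros(k, dtype=bool)
    for j in range(k):
        members = X[labels == j]
        if len(members):
            centroids[j] = members.mean(axis=0)
        else:  # degenerate duplicate-point inputs can leave a label unused
            empty[j] = True
    Xc = X - X.mean(axis=0)
    # first right singular vector = first principal axis
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axis = vt[0]
    scores = np.where(empty, np.inf, centroids @ axis)
    order = np.lexsort((np.linalg.norm(centroids, axis=1), scores))
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int,
    seed: int,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterAssignment:
    """Lloyd k-means over matrix rows with seeded multi-start.

    The best of ``restarts`` seeded initialisations (minimal
    within-cluster sum of squares) is returned; output is deterministic
    given the seed. NaN cells are imputed to 0 first.
    """
    matrix = _impute(matrix)
    X = matrix.to_numpy(dtype=float)
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} outside [1, n_items={len(X)}]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    labels = _canonical_labels(X, raw, k)
    return ClusterAssignment(
        items=[str(i) for i in matrix.index],
        labels=labels,
        k=k,
        seed=seed,
        wcss=float(km.inertia_),
    )


def cluster_as_types(
    matrix: pd.DataFrame, k: int = 2, seed: int = 0, restarts: int = DEFAULT_RESTARTS
) -> ClusterAssignment:
    """Cluster AS event types by their (feature x bin) association vectors.

    ``matrix`` is the signed log-p features x (event_type, bin) table;
    it is transposed so each event type becomes one row vector of all
    feature/bin entries.
    """
    if not isinstance(matrix.columns, pd.MultiIndex):
        raise ValueError("expected (event_type, bin) MultiIndex columns")
    by_type = _impute(matrix).T.unstack(level="bin")  # event_type x (feature, bin)
    if by_type.isna().any().any():
        raise ValueError("matrix incomplete over event types")
    degenerate = by_type.nunique().le(1).all()
    if degenerate:
        logger.warning("all event-type vectors identical: clustering is degenerate")
    return kmeans_cluster(by_type, k=k, seed=seed, restarts=restarts)


def classical_mds(matrix: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of matrix rows.

    Double-centres the squared Euclidean distance matrix and returns the
    top-``dims`` coordinates; for Euclidean input the embedding at full
    rank reproduces the pairwise distances exactly. Axes with
    non-positive eigenvalues are dropped (logged), and each retained
    axis's sign is fixed by making its largest-magnitude loading
    positive.
    """
    matrix = _impute(matrix)
    X = matrix.to_numpy(dtype=float)
    n = len(X)
    if n < dims + 1:
        raise ValueError("need at least dims+1 items")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    avail = int(pos.sum())
    if avail < dims:
        logger.warning("rank %d < requested dims %d; returning fewer axes", avail, dims)
    d = min(dims, avail)
    coords = evecs[:, :d] * np.sqrt(evals[:d])
    for j in range(d):
        if np.abs(coords[:, j]).max() > 0 and coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=matrix.index, columns=[f"dim{j + 1}" for j in range(d)]
    )
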