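"""Spatial-domain detection on the inferred factors.

Domains are found by community detection on a neighbor graph built in factor
space: a shared-nearest-neighbor (SNN) graph cut with the Walktrap
dendrogram, or an unweighted symmetric k-nearest-neighbor graph clustered
with Louvain. When the community count misses the requested number of
domains, the Walktrap dendrogram cut (directly) or the Louvain resolution
(by bisection) is adjusted. An optional refinement pass relabels each spot
to the strict majority label of its spatial neighborhood (itself plus its
nearest spots), evaluated simultaneously against the pre-pass labeling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import igraph as ig
import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .kernels import SpatialCoordinates

__all__ = [
    "DomainLabeling",
    "cluster_pcs",
    "choose_cluster_number",
    "refine_labels",
]

Method = Literal["walktrap_snn", "louvain_knn"]

DEFAULT_KNN_K = 10
_RESOLUTION_RANGE = (0.01, 5.0)
_MAX_ATTEMPTS = 50


@dataclass
class DomainLabeling:
    """Per-location integer domain labels (1..C) with provenance."""

    labels: np.ndarray
    method: Method
    refined: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("labels must form a contiguous set 1..C")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _relabel_contiguous(membership: np.ndarray) -> np.ndarray:
    _, labels = np.unique(membership, return_inverse=True)
    return labels + 1


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0])).fit(X)
    _, idx = nn.kneighbors(X)
    return idx[:, 1:]  # drop self


def _snn_graph(X: np.ndarray, k: int) -> ig.Graph:
    """SNN graph: weight = |shared kNN| / (2k - |shared kNN|), zeros dropped."""
    n = X.shape[0]
    idx = _knn_indices(X, k)
    neigh_sets = [set(row) for row in idx]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            shared = len(neigh_sets[a] & neigh_sets[b])
            if shared > 0:
                edges.append((a, b))
                weights.append(shared / (2 * k - shared))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def _knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    n = X.shape[0]
    idx = _knn_indices(X, k)
    edges = {(min(i, int(j)), max(i, int(j))) for i in range(n) for j in idx[i]}
    return ig.Graph(n=n, edges=sorted(edges))


def cluster_pcs(
    Z: np.ndarray,
    method: Method = "walktrap_snn",
    target_clusters: int = 2,
    knn_k: int = DEFAULT_KNN_K,
    seed: int = 0,
) -> DomainLabeling:
    """Cluster locations (columns of ``Z``) into ``target_clusters`` domains."""
    X = np.asarray(Z, float).T  # locations x factors
    n = X.shape[0]
    if not 2 <= target_clusters <= n:
        raise ValueError(f"target_clusters={target_clusters} out of range for n={n}")
    ig.set_random_number_generator(random.Random(seed))
    if method == "walktrap_snn":
        g = _snn_graph(X, knn_k)
        dendro = g.community_walktrap(weights=g.es["weight"] if g.ecount() else None)
        floor = g.vcount() - len(dendro.merges)  # components left after all merges
        if target_clusters < floor:
            raise ValueError(
                f"walktrap cannot produce {target_clusters} clusters; "
                f"achievable range is [{floor}, {g.vcount()}]"
            )
        membership = np.asarray(dendro.as_clustering(n=target_clusters).membership)
    elif method == "louvain_knn":
        g = _knn_graph(X, knn_k)
        lo, hi = _RESOLUTION_RANGE

        def communities(res: float) -> np.ndarray:
            ig.set_random_number_generator(random.Random(seed))
            return np.asarray(g.community_multilevel(resolution=res).membership)

        membership = None
        for _ in range(_MAX_ATTEMPTS):
            mid = 0.5 * (lo + hi)
            mem = communities(mid)
            c = len(np.unique(mem))
            if c == target_clusters:
                membership = mem
                break
            if c < target_clusters:
                lo = mid  # need finer communities
            else:
                hi = mid
        if membership is None:
            c_lo = len(np.unique(communities(_RESOLUTION_RANGE[0])))
            c_hi = len(np.unique(communities(_RESOLUTION_RANGE[1])))
            raise ValueError(
                f"louvain could not reach {target_clusters} clusters; "
                f"achievable range is about [{c_lo}, {c_hi}]"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return DomainLabeling(_relabel_contiguous(membership), method=method)


def choose_cluster_number(
    Z: np.ndarray,
    candidates: Sequence[int],
    coords: SpatialCoordinates | None = None,
    method: Method = "walktrap_snn",
    knn_k: int = DEFAULT_KNN_K,
    seed: int = 0,
) -> int:
    """Candidate cluster count with the highest mean silhouette width.

    Silhouette widths are computed on Euclidean distances in factor space;
    ties break toward the smaller count, and candidates whose clustering
    leaves the silhouette undefined (singleton clusters) are skipped.
    """
    X = np.asarray(Z, float).T
    best_c, best_score = None, -np.inf
    for c in sorted(candidates):
        try:
            labeling = cluster_pcs(
                Z, method=method, target_clusters=c, knn_k=knn_k, seed=seed
            )
        except ValueError:
            continue
        labels = labeling.labels
        counts = np.bincount(labels)[1:]
        if (counts == 1).any() or len(counts) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score + 1e-12:  # strict improvement: ties keep smaller c
            best_c, best_score = c, score
    if best_c is None:
        raise ValueError("no candidate produced a valid silhouette score")
    return best_c


def refine_labels(
    labeling: DomainLabeling,
    coords: SpatialCoordinates,
    neighbor_count: int = 6,
) -> DomainLabeling:
    """Majority-vote spatial refinement (single simultaneous pass).

    Each spot is compared against its ``neighbor_count`` spatially nearest
    spots plus itself; if a strict majority label exists and differs from the
    spot's own, the spot is relabeled. All votes use the pre-pass labeling.
    """
    if neighbor_count < 1:
        raise ValueError("neighbor_count must be >= 1")
    labels = labeling.labels
    n = labels.size
    if coords.n != n:
        raise ValueError("coordinate and label counts differ")
    idx = _knn_indices(coords.coords, min(neighbor_count, n - 1))
    new_labels = labels.copy()
    for i in range(n):
        votes = np.concatenate(([labels[i]], labels[idx[i]]))
        values, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        if top > votes.size / 2:  # strict majority
            winner = values[counts == top][0]
            new_labels[i] = winner
    return replace(labeling, labels=_relabel_contiguous(new_labels), refined=True)
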