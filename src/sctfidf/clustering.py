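"""Clustering back-ends.

Point-based clusterers (k-means, spherical k-means, EM Gaussian
mixtures) take a cells x features array with cells as rows.  Ward
hierarchical clustering and the graph community methods operate on a
precomputed :class:`~sctfidf.distances.DistanceMatrix`.  Every back-end
is deterministic given (input, seed) and returns contiguous 0-based
cluster ids ordered by first occurrence.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import igraph as ig
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.metrics import silhouette_samples
from sklearn.mixture import GaussianMixture

from .distances import DistanceMatrix

__all__ = [
    "ClusterAssignment",
    "CellGraph",
    "kmeans",
    "spherical_kmeans",
    "gmm_em",
    "hierarchical_ward",
    "build_cell_graph",
    "cluster_graph",
    "per_cluster_silhouette",
    "recursive_partition",
]

logger = logging.getLogger(__name__)

DEFAULT_GRAPH_CUTOFF = 0.01
DEFAULT_SILHOUETTE_THRESHOLD = 0.25
MIN_SPLITTABLE = 3
_EPS_WEIGHT = 1e-12


def relabel_contiguous(labels) -> np.ndarray:
    """Map labels to contiguous 0-based ids ordered by first occurrence."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = relabel_contiguous(self.labels)

    @property
    def k(self) -> int:
        return int(len(np.unique(self.labels)))

    @property
    def n(self) -> int:
        return int(len(self.labels))


# ----------------------------------------------------------------------
# point-based clusterers


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of cells {n}")


def kmeans(x: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """Lloyd k-means with k-means++ init and 10 restarts."""
    x = np.asarray(x, dtype=float)
    _check_k(k, x.shape[0])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterAssignment(labels, "kmeans", {"k": k, "seed": seed})


def spherical_kmeans(
    x: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> ClusterAssignment:
    """K-means under the cosine dissimilarity objective.

    Columns are L2-normalized and Lloyd iterations run with centroids
    projected back to the unit sphere after every mean update; the
    assignment is therefore invariant to positive rescaling of any cell.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    _check_k(k, n)
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm cell row(s) at indices {bad[:5].tolist()}")
    xn = x / norms[:, None]
    rng = np.random.RandomState(seed)
    best_labels, best_obj = None, np.inf
    for _ in range(n_restarts):
        centers, _ = kmeans_plusplus(xn, n_clusters=k, random_state=rng)
        cn = np.linalg.norm(centers, axis=1)
        centers = centers / np.where(cn == 0, 1.0, cn)[:, None]
        labels = None
        for _it in range(max_iter):
            sim = xn @ centers.T
            new_labels = np.argmax(sim, axis=1)  # ties -> lowest index
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if not members.any():
                    # re-seed empty cluster with the farthest point
                    far = int(np.argmin(sim[np.arange(n), labels]))
                    centers[c] = xn[far]
                    continue
                mean = xn[members].mean(axis=0)
                norm = np.linalg.norm(mean)
                if norm > 0:
                    centers[c] = mean / norm
        obj = float(np.sum(1.0 - (xn @ centers.T)[np.arange(n), labels]))
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels.copy()
    return ClusterAssignment(
        best_labels, "spherical_kmeans", {"k": k, "seed": seed}
    )


def gmm_em(x: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """EM fit of a k-component Gaussian mixture, hard max-posterior labels.

    Full covariances with 5 seeded restarts; on numerical failure the fit
    falls back to diagonal covariances with a warning.
    """
    x = np.asarray(x, dtype=float)
    _check_k(k, x.shape[0])
    try:
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=5, random_state=seed
        )
        labels = gm.fit_predict(x)
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"full-covariance GMM failed ({exc}); falling back to diagonal",
            RuntimeWarning,
        )
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", n_init=5, random_state=seed
        )
        labels = gm.fit_predict(x)
    return ClusterAssignment(labels, "gmm_em", {"k": k, "seed": seed})


# ----------------------------------------------------------------------
# hierarchical Ward on precomputed distances


def hierarchical_ward(d: DistanceMatrix | np.ndarray, k: int) -> ClusterAssignment:
    """Agglomerative clustering with the Ward (Lance-Williams) update
    applied directly to the given dissimilarities, cut at k clusters."""
    if isinstance(d, DistanceMatrix):
        metric = d.metric
        dm = d.d
    else:
        metric = "euclidean"
        dm = np.asarray(d, dtype=float)
        if dm.ndim != 2 or dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
            raise ValueError("expected a symmetric square distance matrix")
    n = dm.shape[0]
    _check_k(k, n)
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dm, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(labels, "hierarchical_ward", {"k": k, "metric": metric})


# ----------------------------------------------------------------------
# graph construction and community detection


@dataclass
class CellGraph:
    """Weighted undirected cell graph (no self-loops, weights > 0)."""

    n: int
    edges: list[tuple[int, int]]
    weights: np.ndarray
    metric: str
    cell_ids: list[str] | None = None


def build_cell_graph(d: DistanceMatrix, cutoff: float = DEFAULT_GRAPH_CUTOFF) -> CellGraph:
    """Threshold min-max scaled distances into a dense weighted graph.

    Distances are scaled to [0, 1]; every pair with scaled distance >=
    ``cutoff`` becomes an edge weighted by the similarity 1 - scaled
    distance (floored at a tiny positive value so weights stay > 0).
    """
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must be in [0, 1)")
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 cells")
    iu = np.triu_indices(n, k=1)
    vals = d.d[iu]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("all pairwise distances equal; graph scaling degenerate")
    scaled = (vals - lo) / (hi - lo)
    keep = scaled >= cutoff
    edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    weights = np.maximum(1.0 - scaled[keep], _EPS_WEIGHT)
    return CellGraph(
        n=n, edges=edges, weights=weights, metric=d.metric, cell_ids=d.cell_ids
    )


def cluster_graph(
    g: CellGraph, algorithm: str = "louvain", seed: int = 0
) -> ClusterAssignment:
    """Weighted modularity community detection.

    ``greedy`` is agglomerative CNM-style merging (cut at the maximum
    modularity), ``louvain`` is multilevel local moving.  Cluster count
    is determined internally.
    """
    if algorithm not in ("greedy", "louvain"):
        raise ValueError("algorithm must be 'greedy' or 'louvain'")
    if g.n == 0:
        raise ValueError("empty graph")
    graph = ig.Graph(n=g.n, edges=g.edges)
    weights = list(map(float, g.weights))
    ig.set_random_number_generator(random.Random(seed))
    try:
        if algorithm == "greedy":
            dendro = graph.community_fastgreedy(weights=weights or None)
            clustering = dendro.as_clustering()
        else:
            clustering = graph.community_multilevel(weights=weights or None)
    finally:
        ig.set_random_number_generator(random)
    return ClusterAssignment(
        np.asarray(clustering.membership), f"graph_{algorithm}", {"seed": seed}
    )


# ----------------------------------------------------------------------
# silhouette-driven recursive re-partitioning


def per_cluster_silhouette(d: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Mean silhouette per cluster on a precomputed distance matrix.

    With a single cluster the silhouette is undefined; the cluster is
    reported as -1 so that it always falls below any sensible threshold.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        return {int(uniq[0]): -1.0}
    sil = silhouette_samples(d, labels, metric="precomputed")
    return {int(c): float(sil[labels == c].mean()) for c in uniq}


def recursive_partition(
    counts,
    pipeline,
    base: ClusterAssignment,
    min_k: int = 1,
    silhouette_threshold: float = DEFAULT_SILHOUETTE_THRESHOLD,
    seed: int = 0,
) -> ClusterAssignment:
    """Refine ``base`` by re-clustering low-silhouette clusters.

    ``pipeline`` must provide ``distances(counts) -> (n, n) array`` (the
    metric used for silhouettes), ``cluster(counts, seed) -> labels``
    (the full re-transformation + clustering applied to a cell subset)
    and optionally ``fallback_split(counts) -> labels`` used to enforce
    ``min_k`` when the community method refuses to split.

    Splitting enforces the minimum cluster count: while k < min_k the
    lowest-silhouette cluster below the threshold (or, if none is below,
    the lowest-silhouette splittable cluster) is re-clustered on its own
    re-transformed submatrix.  The loop stops as soon as k >= min_k or
    no cluster can be split.  The number of clusters never decreases and
    sub-clusters smaller than 3 cells are never re-partitioned.
    """
    if min_k < 1:
        raise ValueError("min_k must be >= 1")
    labels = base.labels.copy()
    n = len(labels)
    d_full = np.asarray(pipeline.distances(counts), dtype=float)
    unsplittable: set[int] = set()

    for _ in range(2 * n):
        uniq, counts_per = np.unique(labels, return_counts=True)
        k = uniq.size
        sil = per_cluster_silhouette(d_full, labels)
        sizes = dict(zip(uniq.tolist(), counts_per.tolist()))
        splittable = [
            c
            for c in uniq.tolist()
            if sizes[c] >= MIN_SPLITTABLE and c not in unsplittable
        ]
        if k >= min_k:
            break
        below = [c for c in splittable if sil[c] < silhouette_threshold]
        # prefer sub-threshold clusters, but keep enforcing the floor
        candidates = below if below else splittable
        if not candidates:
            break
        target = min(candidates, key=lambda c: sil[c])
        members = np.flatnonzero(labels == target)
        sub = counts.subset(cell_idx=members)
        try:
            sub_labels = relabel_contiguous(pipeline.cluster(sub, seed))
        except ValueError as exc:
            logger.info("re-clustering of cluster %d failed: %s", target, exc)
            sub_labels = np.zeros(len(members), dtype=int)
        if len(np.unique(sub_labels)) < 2 and k < min_k and hasattr(
            pipeline, "fallback_split"
        ):
            try:
                sub_labels = relabel_contiguous(pipeline.fallback_split(sub))
            except ValueError as exc:
                logger.info("fallback split of cluster %d failed: %s", target, exc)
        if len(np.unique(sub_labels)) < 2:
            unsplittable.add(target)
            continue
        next_id = labels.max() + 1
        for new in np.unique(sub_labels):
            if new == 0:
                continue  # first sub-cluster keeps the old id
            labels[members[sub_labels == new]] = next_id
            next_id += 1
    refined = ClusterAssignment(
        labels,
        base.method + "+recursive",
        {
            **base.params,
            "min_k": min_k,
            "silhouette_threshold": silhouette_threshold,
        },
    )
    assert refined.k >= base.k
    return refined
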