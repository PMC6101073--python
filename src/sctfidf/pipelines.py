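"""Named clustering method compositions.

Each method name (e.g. ``TF-IDF_Bin_Louvain_C``) maps to a front-end
transformation of the count matrix plus a clustering back-end:

* front-ends: ``log`` (log2(x+1)), ``log_pca`` (log + top-10 PCs),
  ``tsne`` (log + 2-D tSNE), ``tfidf_top`` / ``tfidf_var`` (TF-IDF
  scores restricted to selected genes), ``tfidf_bin`` (binarized
  TF-IDF signatures);
* back-ends: k-means, spherical k-means, EM-GMM, Ward hierarchical
  clustering on Euclidean/Pearson/cosine/Jaccard distances, and dense
  weighted-graph greedy/Louvain modularity clustering followed by
  silhouette-driven recursive re-partitioning.

``k="auto"`` resolves the number of clusters with the gap statistic on
the method's own transformed representation; graph methods determine
their cluster count internally and are only floored at a minimum k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from . import clustering as cl
from . import tfidf as tf
from .distances import DistanceMatrix, pairwise
from .io_matrix import CountMatrix
from .model_selection import gap_statistic

__all__ = [
    "PipelineConfig",
    "MethodSpec",
    "METHOD_REGISTRY",
    "FINAL_METHODS",
    "list_methods",
    "log_transform",
    "pca_front",
    "run_method",
]


@dataclass
class PipelineConfig:
    n_pcs: int = 10
    tsne_perplexity: float = 30.0
    top_cap: float = tf.DEFAULT_TOP_CAP
    var_fraction: float = tf.DEFAULT_VAR_FRACTION
    binarize_multiplier: float = tf.DEFAULT_BINARIZE_MULTIPLIER
    graph_cutoff: float = cl.DEFAULT_GRAPH_CUTOFF
    silhouette_threshold: float = cl.DEFAULT_SILHOUETTE_THRESHOLD
    min_k: int = 1
    gap_k_max: int = 10
    gap_b_refs: int = 50


@dataclass(frozen=True)
class MethodSpec:
    name: str
    frontend: str  # log | log_pca | tsne | tfidf_top | tfidf_var | tfidf_bin
    backend: str  # kmeans | skmeans | gmm | hc | greedy | louvain
    metric: str | None = None  # for hc / graph backends


_METRIC_SUFFIX = {"E": "euclidean", "P": "pearson", "C": "cosine", "J": "jaccard"}


def _build_registry() -> dict[str, MethodSpec]:
    specs: list[MethodSpec] = [
        MethodSpec("Log_Kmeans", "log", "kmeans"),
        MethodSpec("Log_PCA_Kmeans", "log_pca", "kmeans"),
        MethodSpec("Log_PCA_GMM", "log_pca", "gmm"),
        MethodSpec("Log_PCA_sKmeans", "log_pca", "skmeans"),
        MethodSpec("Log_PCA_HC_E", "log_pca", "hc", "euclidean"),
        MethodSpec("Log_PCA_HC_P", "log_pca", "hc", "pearson"),
        MethodSpec("tSNE_Kmeans", "tsne", "kmeans"),
        MethodSpec("tSNE_HC_E", "tsne", "hc", "euclidean"),
        MethodSpec("tSNE_HC_P", "tsne", "hc", "pearson"),
        MethodSpec("Log_Louvain_E", "log", "louvain", "euclidean"),
    ]
    for sel in ("Top", "Var"):
        fe = f"tfidf_{sel.lower()}"
        specs += [
            MethodSpec(f"TF-IDF_{sel}_GMM", fe, "gmm"),
            MethodSpec(f"TF-IDF_{sel}_Kmeans", fe, "kmeans"),
            MethodSpec(f"TF-IDF_{sel}_sKmeans", fe, "skmeans"),
        ]
        for suf in ("E", "P", "C"):
            specs.append(
                MethodSpec(f"TF-IDF_{sel}_HC_{suf}", fe, "hc", _METRIC_SUFFIX[suf])
            )
    for backend in ("HC", "Greedy", "Louvain"):
        for suf in ("E", "P", "C", "J"):
            specs.append(
                MethodSpec(
                    f"TF-IDF_Bin_{backend}_{suf}",
                    "tfidf_bin",
                    backend.lower() if backend != "HC" else "hc",
                    _METRIC_SUFFIX[suf],
                )
            )
    return {s.name: s for s in specs}


METHOD_REGISTRY: dict[str, MethodSpec] = _build_registry()

# the low-accuracy methods dropped after the 2-class screen; the
# remaining 26 form the final comparison set
_SCREENED_OUT = {
    "tSNE_HC_P",
    "Log_Kmeans",
    "Log_PCA_sKmeans",
    "TF-IDF_Top_GMM",
    "TF-IDF_Var_GMM",
    "TF-IDF_Var_HC_E",
    "TF-IDF_Var_HC_P",
    "TF-IDF_Var_HC_C",
}
FINAL_METHODS: list[str] = [
    name for name in METHOD_REGISTRY if name not in _SCREENED_OUT
]


def list_methods(final_only: bool = False) -> list[str]:
    return list(FINAL_METHODS) if final_only else list(METHOD_REGISTRY)


# ----------------------------------------------------------------------
# front-ends


def log_transform(m) -> np.ndarray:
    """Elementwise log2(x+1); accepts a CountMatrix or raw array."""
    if isinstance(m, CountMatrix):
        m = m.values
    if sp.issparse(m):
        m = np.asarray(m.todense())
    return np.log2(np.asarray(m, dtype=float) + 1.0)


def pca_front(m: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Project cells (columns of the genes x cells input) onto the top
    principal axes; returns cells x n_components scores (centered, not
    scaled)."""
    x = np.asarray(m, dtype=float).T
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(x.shape)}"
        )
    return PCA(n_components=n_components, svd_solver="full").fit_transform(x)


def _tsne_front(log_mat: np.ndarray, seed: int, perplexity: float) -> np.ndarray:
    x = log_mat.T  # cells x genes
    perp = min(perplexity, max(2.0, (x.shape[0] - 1) / 3.0))
    return TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca"
    ).fit_transform(x)


def _features(
    m: CountMatrix, frontend: str, seed: int, cfg: PipelineConfig
) -> np.ndarray:
    """Cells x features representation for the given front-end."""
    if frontend == "log":
        return log_transform(m).T
    if frontend == "log_pca":
        log = log_transform(m)
        return pca_front(log, min(cfg.n_pcs, min(log.shape)))
    if frontend == "tsne":
        return _tsne_front(log_transform(m), seed, cfg.tsne_perplexity)
    t = tf.compute_tfidf(m)
    if frontend == "tfidf_top":
        sel = tf.select_genes_top(t, max_genes=cfg.top_cap)
        return t.subset_genes(sel.indices_in(t.gene_ids)).to_dense().T
    if frontend == "tfidf_var":
        sel = tf.select_genes_var(t, keep_fraction=cfg.var_fraction)
        return t.subset_genes(sel.indices_in(t.gene_ids)).to_dense().T
    if frontend == "tfidf_bin":
        sig = tf.binarize(t, multiplier=cfg.binarize_multiplier, on_empty="zero")
        return sig.to_dense().T
    raise ValueError(f"unknown frontend {frontend!r}")


def _point_distances(x: np.ndarray, metric: str, cell_ids=None) -> DistanceMatrix:
    """Pairwise distances between rows (cells) of a feature matrix."""
    return pairwise(x.T, metric, cell_ids=cell_ids)


# ----------------------------------------------------------------------
# back-ends

_POINT_CLUSTERERS = {
    "kmeans": cl.kmeans,
    "skmeans": cl.spherical_kmeans,
    "gmm": cl.gmm_em,
}


@dataclass
class GraphPipeline:
    """Re-applicable transform + graph clustering for recursive
    re-partitioning of cell subsets."""

    frontend: str
    metric: str
    algorithm: str  # greedy | louvain
    cfg: PipelineConfig
    seed: int

    def _features(self, m: CountMatrix) -> np.ndarray:
        return _features(m, self.frontend, self.seed, self.cfg)

    def distances(self, m: CountMatrix) -> np.ndarray:
        return _point_distances(self._features(m), self.metric, m.cell_ids).d

    def cluster(self, m: CountMatrix, seed: int) -> np.ndarray:
        d = _point_distances(self._features(m), self.metric, m.cell_ids)
        graph = cl.build_cell_graph(d, cutoff=self.cfg.graph_cutoff)
        return cl.cluster_graph(graph, self.algorithm, seed).labels

    def fallback_split(self, m: CountMatrix) -> np.ndarray:
        d = _point_distances(self._features(m), self.metric, m.cell_ids)
        return cl.hierarchical_ward(d, 2).labels


def _resolve_k_auto(x: np.ndarray, clusterer, seed: int, cfg: PipelineConfig) -> int:
    result = gap_statistic(
        x, clusterer, k_max=cfg.gap_k_max, b_refs=cfg.gap_b_refs, seed=seed
    )
    return result.k_star


def run_method(
    name: str,
    m: CountMatrix,
    k: int | str = "auto",
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> cl.ClusterAssignment:
    """Run the named method composition on a count matrix.

    ``k`` is an integer or ``"auto"`` (gap-statistic selection; for
    graph methods an explicit k acts as the minimum cluster count
    enforced by recursive re-partitioning).
    """
    if name not in METHOD_REGISTRY:
        raise ValueError(
            f"unknown method {name!r}; valid methods: {sorted(METHOD_REGISTRY)}"
        )
    spec = METHOD_REGISTRY[name]
    cfg = config or PipelineConfig()
    x = _features(m, spec.frontend, seed, cfg)
    provenance = {
        "method": name,
        "frontend": spec.frontend,
        "backend": spec.backend,
        "metric": spec.metric,
        "seed": seed,
        "k_requested": k,
    }

    if spec.backend in _POINT_CLUSTERERS:
        clusterer = _POINT_CLUSTERERS[spec.backend]
        if k == "auto":
            k = _resolve_k_auto(x, clusterer, seed, cfg)
        assignment = clusterer(x, int(k), seed)
        assignment.method = name
        assignment.params.update(provenance)
        return assignment

    if spec.backend == "hc":

        def hc_clusterer(xa, kk, sd):
            return cl.hierarchical_ward(_point_distances(xa, spec.metric), kk)

        if k == "auto":
            k = _resolve_k_auto(x, hc_clusterer, seed, cfg)
        d = _point_distances(x, spec.metric, m.cell_ids)
        assignment = cl.hierarchical_ward(d, int(k))
        assignment.method = name
        assignment.params.update(provenance)
        return assignment

    # graph backends: cluster count found internally, floored at min_k
    pipeline = GraphPipeline(spec.frontend, spec.metric, spec.backend, cfg, seed)
    d = _point_distances(x, spec.metric, m.cell_ids)
    graph = cl.build_cell_graph(d, cutoff=cfg.graph_cutoff)
    base = cl.cluster_graph(graph, spec.backend, seed)
    min_k = int(k) if k != "auto" else cfg.min_k
    refined = cl.recursive_partition(
        m,
        pipeline,
        base,
        min_k=min_k,
        silhouette_threshold=cfg.silhouette_threshold,
        seed=seed,
    )
    refined.method = name
    refined.params.update(provenance)
    return refined
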