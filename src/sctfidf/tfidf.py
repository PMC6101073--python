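"""Term-frequency / inverse-document-frequency scoring of count matrices.

Cells are treated as documents and genes as words: the term frequency of
a gene in a cell is its count divided by the cell's maximum count, and
the inverse document frequency of a gene is log2(N / n_i) where n_i is
the number of cells detecting the gene.  The two are multiplied into a
per-(gene, cell) score used for gene selection and binarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture

from .io_matrix import CountMatrix

__all__ = [
    "TfidfMatrix",
    "BinarySignatureMatrix",
    "GeneSelection",
    "compute_tf",
    "compute_idf",
    "compute_tfidf",
    "select_genes_top",
    "select_genes_var",
    "binarize",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_CAP = 3000
DEFAULT_VAR_FRACTION = 0.30
DEFAULT_BINARIZE_MULTIPLIER = 0.1


@dataclass
class TfidfMatrix:
    """Genes x cells TF-IDF scores together with the per-gene IDF vector."""

    scores: sp.csr_matrix
    idf: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cells(self) -> int:
        return self.scores.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.scores.todense(), dtype=float)

    def subset_genes(self, gene_idx) -> "TfidfMatrix":
        gene_idx = np.asarray(gene_idx)
        return TfidfMatrix(
            scores=self.scores[gene_idx, :].copy(),
            idf=self.idf[gene_idx].copy(),
            gene_ids=[self.gene_ids[i] for i in gene_idx],
            cell_ids=list(self.cell_ids),
        )


@dataclass
class BinarySignatureMatrix:
    """Genes x cells 0/1 expression signatures and the per-cell cutoffs."""

    signatures: sp.csr_matrix
    cutoff_used: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.signatures.todense(), dtype=float)


@dataclass
class GeneSelection:
    selected_gene_ids: list[str]
    method: str  # "top" | "var"
    diagnostics: dict = field(default_factory=dict)

    def indices_in(self, gene_ids: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(gene_ids)}
        return np.asarray([pos[g] for g in self.selected_gene_ids], dtype=int)


# ----------------------------------------------------------------------


def _column_max(values: sp.spmatrix) -> np.ndarray:
    return np.asarray(values.max(axis=0).todense()).ravel()


def compute_tf(m: CountMatrix) -> sp.csr_matrix:
    """Per-cell term frequencies: each count divided by the cell's max count."""
    col_max = _column_max(m.values)
    zero_cells = np.flatnonzero(col_max <= 0)
    if zero_cells.size:
        raise ValueError(
            f"cell(s) with all-zero counts: {[m.cell_ids[j] for j in zero_cells[:5]]}"
        )
    tf = m.values.tocsc(copy=True)
    tf.data = tf.data / np.repeat(col_max, np.diff(tf.indptr))
    return tf.tocsr()


def compute_idf(m: CountMatrix) -> np.ndarray:
    """log2(N / n_i) per gene; genes detected in no cell get IDF 0."""
    n_cells = m.n_cells
    if n_cells < 1:
        raise ValueError("need at least one cell")
    n_i = np.asarray((m.values > 0).sum(axis=1)).ravel()
    idf = np.zeros(m.n_genes, dtype=float)
    nz = n_i > 0
    idf[nz] = np.log2(n_cells / n_i[nz])
    return idf


def compute_tfidf(m: CountMatrix) -> TfidfMatrix:
    tf = compute_tf(m)
    idf = compute_idf(m)
    scores = sp.diags(idf) @ tf
    scores = sp.csr_matrix(scores)
    scores.eliminate_zeros()
    return TfidfMatrix(
        scores=scores,
        idf=idf,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
    )


# ----------------------------------------------------------------------
# gene selection


def select_genes_top(
    t: TfidfMatrix,
    max_genes: float = DEFAULT_TOP_CAP,
    detection_counts: np.ndarray | None = None,
    seed: int = 0,
) -> GeneSelection:
    """Select genes in the high-mean component of a 2-part Gaussian
    mixture fitted to per-gene mean TF-IDF scores.

    When more than ``max_genes`` genes fall in the high component, only
    the ``max_genes`` genes detected in the most cells are kept.
    ``detection_counts`` defaults to the number of cells with a nonzero
    score per gene.
    """
    means = np.asarray(t.scores.mean(axis=1)).ravel()
    if t.n_genes < 2 or np.allclose(means, means[0]):
        raise ValueError("degenerate gene means: cannot fit 2-component mixture")
    gmm = GaussianMixture(
        n_components=2, n_init=5, random_state=seed, covariance_type="full"
    )
    comp = gmm.fit_predict(means.reshape(-1, 1))
    high = int(np.argmax(gmm.means_.ravel()))
    selected = np.flatnonzero(comp == high)
    if detection_counts is None:
        detection_counts = np.asarray((t.scores > 0).sum(axis=1)).ravel()
    if np.isfinite(max_genes) and selected.size > max_genes:
        order = np.argsort(-detection_counts[selected], kind="stable")
        selected = selected[order[: int(max_genes)]]
        selected = np.sort(selected)
    return GeneSelection(
        selected_gene_ids=[t.gene_ids[i] for i in selected],
        method="top",
        diagnostics={
            "gene_means": means,
            "component": comp,
            "high_component": high,
            "component_means": gmm.means_.ravel(),
        },
    )


def select_genes_var(
    t: TfidfMatrix, keep_fraction: float = DEFAULT_VAR_FRACTION
) -> GeneSelection:
    """Select highly variable genes by the residual of log CV over the
    log CV-vs-mean regression line.

    Per gene the mean and coefficient of variation (sd/mean, over all
    cells) of the TF-IDF scores are computed; an ordinary least-squares
    line of log(CV) on log(mean) is fitted and the top ``keep_fraction``
    of genes by residual are returned (ties broken by gene order).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    dense = t.to_dense()
    means = dense.mean(axis=1)
    sds = dense.std(axis=1, ddof=1)
    eligible = (means > 0) & (sds > 0)
    n_dropped = int((~eligible).sum())
    if n_dropped:
        logger.info("select_genes_var: excluding %d zero-mean/zero-sd genes", n_dropped)
    idx = np.flatnonzero(eligible)
    if idx.size < 10:
        raise ValueError("need at least 10 genes with nonzero mean and sd")
    cv = sds[idx] / means[idx]
    log_mean = np.log(means[idx])
    log_cv = np.log(cv)
    slope, intercept = np.polyfit(log_mean, log_cv, 1)
    residual = log_cv - (slope * log_mean + intercept)
    n_keep = max(1, int(round(keep_fraction * idx.size)))
    order = np.argsort(-residual, kind="stable")[:n_keep]
    selected = np.sort(idx[order])
    res_full = np.full(t.n_genes, np.nan)
    res_full[idx] = residual
    return GeneSelection(
        selected_gene_ids=[t.gene_ids[i] for i in selected],
        method="var",
        diagnostics={
            "gene_means": means,
            "gene_cv": np.where(means > 0, sds / np.maximum(means, 1e-300), np.nan),
            "residual": res_full,
            "slope": float(slope),
            "intercept": float(intercept),
        },
    )


# ----------------------------------------------------------------------
# binarization


def binarize(
    t: TfidfMatrix,
    multiplier: float = DEFAULT_BINARIZE_MULTIPLIER,
    on_empty: str = "error",
) -> BinarySignatureMatrix:
    """Threshold TF-IDF scores into per-cell 0/1 expression signatures.

    The cutoff for cell j is ``multiplier`` times the mean of the
    nonzero scores in cell j; entries strictly above the cutoff become
    1.  With ``multiplier=0`` the result is exactly the detection mask.

    ``on_empty`` controls cells with no nonzero score: ``"error"``
    raises, ``"zero"`` leaves them as an all-zero signature (used when
    re-binarizing submatrices during recursive partitioning).
    """
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    if on_empty not in ("error", "zero"):
        raise ValueError("on_empty must be 'error' or 'zero'")
    csc = t.scores.tocsc()
    nnz_per_cell = np.diff(csc.indptr)
    empty = np.flatnonzero(nnz_per_cell == 0)
    if empty.size and on_empty == "error":
        raise ValueError(
            "cell(s) with no nonzero TF-IDF score: "
            f"{[t.cell_ids[j] for j in empty[:5]]}"
        )
    sums = np.zeros(t.n_cells)
    np.add.at(sums, np.repeat(np.arange(t.n_cells), nnz_per_cell), csc.data)
    cutoffs = np.zeros(t.n_cells)
    nz = nnz_per_cell > 0
    cutoffs[nz] = multiplier * sums[nz] / nnz_per_cell[nz]
    out = csc.copy()
    out.data = (csc.data > np.repeat(cutoffs, nnz_per_cell)).astype(float)
    out.eliminate_zeros()
    return BinarySignatureMatrix(
        signatures=out.tocsr(),
        cutoff_used=cutoffs,
        gene_ids=list(t.gene_ids),
        cell_ids=list(t.cell_ids),
    )
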