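"""Pairwise distance kernels between cells.

All kernels operate on cells as the columns of a genes x cells matrix;
``pairwise`` returns the full symmetric cell x cell distance matrix.
Degenerate vectors (zero norm, zero variance, all-zero binary) raise
rather than returning a sentinel so that upstream QC failures surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

METRICS = ("euclidean", "pearson", "cosine", "jaccard")

__all__ = [
    "DistanceMatrix",
    "METRICS",
    "cosine_dissimilarity",
    "jaccard_distance",
    "pearson_distance",
    "euclidean_distance",
    "pairwise",
]


@dataclass
class DistanceMatrix:
    """Symmetric cell x cell distance matrix with zero diagonal."""

    d: np.ndarray
    metric: str
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


# ----------------------------------------------------------------------
# scalar kernels


def cosine_dissimilarity(a, b) -> float:
    """1 - cos(angle between a and b); in [0, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm vector in cosine dissimilarity")
    return float(1.0 - (a @ b) / (na * nb))


def jaccard_distance(a, b) -> float:
    """1 - |a AND b| / |a OR b| for binary vectors; in [0, 1]."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    for v in (a, b):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("jaccard distance requires binary vectors")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both vectors all-zero in jaccard distance")
    inter = np.logical_and(a, b).sum()
    return float(1.0 - inter / union)


def pearson_distance(a, b) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance vector in pearson distance")
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def euclidean_distance(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    return float(np.linalg.norm(a - b))


# ----------------------------------------------------------------------
# vectorized pairwise


def _as_cells_by_features(m) -> np.ndarray:
    if sp.issparse(m):
        m = np.asarray(m.todense())
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return m.T  # cells (columns) become rows


def pairwise(m, metric: str, cell_ids: list[str] | None = None) -> DistanceMatrix:
    """All-pairs distances between the columns (cells) of ``m``."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    x = _as_cells_by_features(m)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]

    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero-norm cell(s): {[ids[j] for j in bad[:5]]}")
        xn = x / norms[:, None]
        d = 1.0 - xn @ xn.T
    elif metric == "pearson":
        stds = x.std(axis=1)
        bad = np.flatnonzero(stds == 0)
        if bad.size:
            raise ValueError(f"zero-variance cell(s): {[ids[j] for j in bad[:5]]}")
        c = x - x.mean(axis=1, keepdims=True)
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        d = 1.0 - c @ c.T
    else:  # jaccard
        if not np.isin(x, (0, 1)).all():
            raise ValueError("jaccard metric requires a binary matrix")
        sizes = x.sum(axis=1)
        bad = np.flatnonzero(sizes == 0)
        if bad.size:
            raise ValueError(f"all-zero cell(s): {[ids[j] for j in bad[:5]]}")
        inter = x @ x.T
        union = sizes[:, None] + sizes[None, :] - inter
        d = 1.0 - inter / union

    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, metric=metric, cell_ids=list(ids))
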