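"""Cell and gene quality control.

All operations return submatrices of their input: values are never
modified, only rows (genes) or columns (cells) are dropped.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_matrix import CountMatrix

__all__ = [
    "EmptyResultError",
    "QCWarning",
    "filter_cells",
    "remove_cell_outliers_mad",
    "filter_genes",
    "exclude_genes",
]

DEFAULT_MIN_GENES_PER_CELL = 200
DEFAULT_MIN_UMI_PER_CELL = 0
DEFAULT_MIN_UMI_PER_GENE = 1
DEFAULT_MAD_K = 3.0


class EmptyResultError(ValueError):
    """A filter removed every row or column."""


class QCWarning(UserWarning):
    pass


def filter_cells(
    m: CountMatrix,
    min_genes: int = DEFAULT_MIN_GENES_PER_CELL,
    min_total_umi: float = DEFAULT_MIN_UMI_PER_CELL,
) -> CountMatrix:
    """Keep cells with enough detected genes and large enough total count."""
    if min_genes < 0 or min_total_umi < 0:
        raise ValueError("thresholds must be non-negative")
    detected = np.asarray((m.values > 0).sum(axis=0)).ravel()
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    keep = (detected >= min_genes) & (totals >= min_total_umi)
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell")
    if keep.all():
        return m.subset()
    return m.subset(cell_idx=np.flatnonzero(keep))


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def remove_cell_outliers_mad(
    m: CountMatrix,
    labels: dict[str, str] | None = None,
    k_mad: float = DEFAULT_MAD_K,
) -> CountMatrix:
    """Drop cells far from their group centroid.

    Distances are Euclidean on log2(x+1) profiles; a cell is an outlier
    when its distance exceeds ``median + k_mad * MAD`` of the group's
    distances.  Groups come from ``labels`` (all cells form one group
    when absent); groups smaller than 3 pass through with a warning.
    """
    if labels is not None:
        missing = [c for c in m.cell_ids if c not in labels]
        if missing:
            raise ValueError(f"cells without labels: {missing[:5]}")
        groups: dict[str, list[int]] = {}
        for j, c in enumerate(m.cell_ids):
            groups.setdefault(labels[c], []).append(j)
    else:
        groups = {"__all__": list(range(m.n_cells))}

    log = m.values.copy()
    log.data = np.log2(log.data + 1.0)
    keep = np.ones(m.n_cells, dtype=bool)
    for name, idx in groups.items():
        if len(idx) < 3:
            warnings.warn(
                f"group {name!r} has fewer than 3 cells; not filtered", QCWarning
            )
            continue
        sub = log[:, idx]
        centroid = np.asarray(sub.mean(axis=1)).ravel()
        # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2, computed sparsely
        sq = np.asarray(sub.multiply(sub).sum(axis=0)).ravel()
        dots = np.asarray(sub.T @ centroid).ravel()
        d2 = np.maximum(sq - 2.0 * dots + centroid @ centroid, 0.0)
        dist = np.sqrt(d2)
        if not np.isfinite(k_mad):
            continue
        thr = np.median(dist) + k_mad * _mad(dist)
        for local, j in enumerate(idx):
            if dist[local] > thr:
                keep[j] = False
    if not keep.any():
        raise EmptyResultError("MAD outlier removal removed every cell")
    if keep.all():
        return m.subset()
    return m.subset(cell_idx=np.flatnonzero(keep))


def filter_genes(
    m: CountMatrix,
    min_total: float = DEFAULT_MIN_UMI_PER_GENE,
    k_mad: float = DEFAULT_MAD_K,
) -> CountMatrix:
    """Keep genes with total count >= min_total, then drop high log-total
    outliers beyond ``median + k_mad * MAD``."""
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    keep = totals >= min_total
    if keep.any() and np.isfinite(k_mad):
        logt = np.log2(totals[keep] + 1.0)
        thr = np.median(logt) + k_mad * _mad(logt)
        high = np.zeros_like(keep)
        high[np.flatnonzero(keep)] = logt > thr
        keep &= ~high
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    if keep.all():
        return m.subset()
    return m.subset(gene_idx=np.flatnonzero(keep))


def exclude_genes(m: CountMatrix, names) -> CountMatrix:
    """Drop the named genes (e.g. dominant marker genes); unknown names
    are ignored with a warning."""
    names = set(names)
    if not names:
        return m.subset()
    unknown = names - set(m.gene_ids)
    if unknown:
        warnings.warn(
            f"genes not present in matrix: {sorted(unknown)}", QCWarning
        )
    keep = [i for i, g in enumerate(m.gene_ids) if g not in names]
    if not keep:
        raise EmptyResultError("gene exclusion removed every gene")
    if len(keep) == m.n_genes:
        return m.subset()
    return m.subset(gene_idx=np.asarray(keep))
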