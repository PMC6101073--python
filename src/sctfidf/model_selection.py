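"""Gap-statistic selection of the number of clusters.

The gap at k is the difference between the expected log within-cluster
dispersion under a Monte-Carlo null (uniform over the per-feature
bounding box of the data) and the observed log dispersion; the selected
k is the plain argmax over the candidate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GapResult", "within_dispersion", "gap_statistic"]

DEFAULT_B_REFS = 50
DEFAULT_K_MAX = 10


@dataclass
class GapResult:
    k_grid: list[int]
    gap: np.ndarray
    se: np.ndarray
    k_star: int
    b_refs: int
    log_w_data: np.ndarray

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"k": self.k_grid, "gap": self.gap, "se": self.se})


def within_dispersion(x: np.ndarray, labels) -> float:
    """Normalized within-cluster sum of squared pairwise Euclidean
    distances: sum_r D_r / (2 n_r), equal to the within-cluster sum of
    squared deviations from centroids."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != x.shape[0]:
        raise ValueError("labels length does not match number of points")
    total = 0.0
    for c in np.unique(labels):
        members = x[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {c}")
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total


def _log_w(x: np.ndarray, clusterer, k: int, seed: int) -> float:
    if k == 1:
        labels = np.zeros(x.shape[0], dtype=int)
    else:
        result = clusterer(x, k, seed)
        labels = getattr(result, "labels", result)
    w = within_dispersion(x, labels)
    if w <= 0:
        return -np.inf
    return float(np.log(w))


def gap_statistic(
    x: np.ndarray,
    clusterer,
    k_max: int = DEFAULT_K_MAX,
    b_refs: int = DEFAULT_B_REFS,
    seed: int = 0,
) -> GapResult:
    """Gap statistic over k = 1..k_max.

    ``clusterer(x, k, seed)`` must return per-point labels (or an object
    with a ``labels`` attribute).  ``b_refs`` reference datasets are
    drawn uniformly from the per-feature bounding box of ``x`` and
    clustered with the same clusterer.  Candidate k whose observed
    dispersion is exactly zero are excluded with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 points")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if b_refs < 2:
        raise ValueError("b_refs must be >= 2")
    k_max = min(k_max, x.shape[0])
    k_grid = list(range(1, k_max + 1))

    log_w_data = np.array([_log_w(x, clusterer, k, seed) for k in k_grid])

    rng = np.random.default_rng(seed)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    log_w_ref = np.empty((b_refs, len(k_grid)))
    for b in range(b_refs):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        log_w_ref[b] = [_log_w(ref, clusterer, k, ref_seed) for k in k_grid]

    gap = log_w_ref.mean(axis=0) - log_w_data
    se = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / b_refs)

    valid = np.isfinite(log_w_data)
    if not valid.all():
        excluded = [k_grid[i] for i in np.flatnonzero(~valid)]
        warnings.warn(f"excluding k={excluded}: zero within-cluster dispersion")
    if not valid.any():
        raise ValueError("no valid k: data dispersion is zero everywhere")
    masked = np.where(valid, gap, -np.inf)
    k_star = k_grid[int(np.argmax(masked))]
    return GapResult(
        k_grid=k_grid,
        gap=gap,
        se=se,
        k_star=k_star,
        b_refs=b_refs,
        log_w_data=log_w_data,
    )
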