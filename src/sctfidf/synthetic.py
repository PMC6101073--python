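"""Synthetic cell-type mixtures for testing the clustering pipelines.

Counts are drawn from a negative binomial whose mean is elevated by
``marker_fold`` on each type's marker genes, then thinned by a logistic
dropout whose detection probability increases with the mean — emulating
the heavy zero-inflation of UMI data.  ``similarity`` controls the
fraction of marker genes shared between cell types, giving the three
difficulty tiers (dissimilar / intermediate / highly similar pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io_matrix import CountMatrix

__all__ = ["MixtureSpec", "generate_mixture", "similarity_tiers", "ratio_counts"]

# detection probability is logistic in log(mean), centered at this mean
_DROPOUT_MIDPOINT = 0.1

SIMILARITY_TIERS = {"dissimilar": 0.0, "intermediate": 0.5, "similar": 0.8}


@dataclass
class MixtureSpec:
    n_types: int = 2
    cells_per_type: tuple[int, ...] = (500, 500)
    n_genes: int = 2000
    n_markers_per_type: int = 50
    marker_fold: float = 20.0
    similarity: float = 0.0
    baseline_mean: float = 0.3
    dispersion: float = 0.5
    dropout_logit_slope: float = 1.0
    seed: int = 0
    marker_offset: int = 0  # first gene index used for marker blocks

    def __post_init__(self) -> None:
        self.cells_per_type = tuple(int(c) for c in self.cells_per_type)
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("each type needs at least one cell")
        if not 0 <= self.similarity <= 1:
            raise ValueError("similarity must be in [0, 1]")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        n_shared = round(self.similarity * self.n_markers_per_type)
        n_unique = self.n_markers_per_type - n_shared
        if self.marker_offset + n_shared + self.n_types * n_unique > self.n_genes:
            raise ValueError("marker allocation exceeds number of genes")

    @property
    def n_cells(self) -> int:
        return sum(self.cells_per_type)

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureSpec":
        data = json.loads(text)
        if "cells_per_type" in data:
            data["cells_per_type"] = tuple(data["cells_per_type"])
        return cls(**data)


def ratio_counts(ratio: tuple[int, int], total: int = 1000) -> tuple[int, int]:
    """Cell counts for a 2-type mixture, e.g. (7, 1) with 1000 cells ->
    (875, 125)."""
    a, b = ratio
    n_a = round(total * a / (a + b))
    return n_a, total - n_a


def _marker_sets(spec: MixtureSpec) -> list[np.ndarray]:
    """Gene indices of each type's markers; the first genes form a pool
    shared by all types according to ``similarity``."""
    n_shared = round(spec.similarity * spec.n_markers_per_type)
    n_unique = spec.n_markers_per_type - n_shared
    shared = spec.marker_offset + np.arange(n_shared)
    sets = []
    offset = spec.marker_offset + n_shared
    for _ in range(spec.n_types):
        unique = np.arange(offset, offset + n_unique)
        sets.append(np.concatenate([shared, unique]))
        offset += n_unique
    return sets


def generate_mixture(spec: MixtureSpec) -> tuple[CountMatrix, dict[str, str]]:
    """Draw a genes x cells count matrix and its ground-truth mapping."""
    rng = np.random.default_rng(spec.seed)
    markers = _marker_sets(spec)

    mean = np.full((spec.n_genes, spec.n_types), spec.baseline_mean)
    for t, m_idx in enumerate(markers):
        mean[m_idx, t] *= spec.marker_fold

    blocks = []
    truth: dict[str, str] = {}
    cell_ids: list[str] = []
    idx = 0
    r = spec.dispersion
    for t, n_cells_t in enumerate(spec.cells_per_type):
        mu = np.repeat(mean[:, t][:, None], n_cells_t, axis=1)
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        # logistic dropout: detection probability rises with the mean
        logit = spec.dropout_logit_slope * np.log(mu / _DROPOUT_MIDPOINT)
        detect_p = 1.0 / (1.0 + np.exp(-logit))
        counts = counts * (rng.random(counts.shape) < detect_p)
        blocks.append(sp.csr_matrix(counts.astype(float)))
        for _ in range(n_cells_t):
            cid = f"cell_{idx:05d}"
            cell_ids.append(cid)
            truth[cid] = f"type_{t}"
            idx += 1
    values = sp.hstack(blocks).tocsr()
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    return (
        CountMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, unit="umi"),
        truth,
    )


def concat_mixtures(
    parts: list[tuple[CountMatrix, dict[str, str]]]
) -> tuple[CountMatrix, dict[str, str]]:
    """Column-concatenate mixtures over the same gene space, re-keying
    cells and prefixing truth labels with the part index.

    Lets tests compose populations with pair-structured similarity, e.g.
    a highly similar pair (one part, high ``similarity``) plus a distinct
    outgroup (a second part with a different ``marker_offset``).
    """
    gene_ids = parts[0][0].gene_ids
    for m, _ in parts[1:]:
        if m.gene_ids != gene_ids:
            raise ValueError("all parts must share the same gene space")
    values = sp.hstack([m.values for m, _ in parts]).tocsr()
    cell_ids: list[str] = []
    truth: dict[str, str] = {}
    idx = 0
    for p, (m, part_truth) in enumerate(parts):
        for old in m.cell_ids:
            cid = f"cell_{idx:05d}"
            cell_ids.append(cid)
            truth[cid] = f"p{p}_{part_truth[old]}"
            idx += 1
    return (
        CountMatrix(values=values, gene_ids=list(gene_ids), cell_ids=cell_ids),
        truth,
    )


def similarity_tiers(spec: MixtureSpec) -> dict[str, MixtureSpec]:
    """The same spec at the three difficulty tiers (similarity 0/0.5/0.8)."""
    return {
        name: replace(spec, similarity=sim) for name, sim in SIMILARITY_TIERS.items()
    }
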