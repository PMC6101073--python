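"""Readers and writers for count matrices, labels and cluster assignments.

Matrices are stored genes x cells: genes play the role of "words" and
cells the role of "documents" throughout the package.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

UNITS = ("umi", "read_count", "rpkm")

__all__ = [
    "CountMatrix",
    "MatrixFormatError",
    "MatrixInputError",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_dense_csv",
    "write_dense_csv",
    "read_labels",
    "write_labels",
    "write_assignment",
    "read_assignment",
]


class MatrixFormatError(ValueError):
    """Raised when an input file is malformed or internally inconsistent."""


class MatrixInputError(FileNotFoundError):
    """Raised when a required input file is missing."""


@dataclass
class CountMatrix:
    """A sparse genes x cells matrix of non-negative expression values.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix (or dense array, converted on init) of
        shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    unit
        One of ``"umi"``, ``"read_count"`` or ``"rpkm"``.  Integer values
        are enforced for the two count units.
    gene_symbols
        Optional mapping from (possibly de-duplicated) gene id to the
        original symbol found in the source file.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "umi"
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise MatrixFormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise MatrixFormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise MatrixFormatError("duplicate cell ids")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        data = self.values.data
        if data.size and data.min() < 0:
            raise ValueError("count matrix contains negative values")
        if self.unit in ("umi", "read_count") and data.size:
            if not np.allclose(data, np.round(data)):
                raise ValueError(f"non-integer values with unit={self.unit!r}")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        """Return the submatrix at the given row/column integer indices."""
        vals = self.values
        gene_ids = self.gene_ids
        cell_ids = self.cell_ids
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            vals = vals[gene_idx, :]
            gene_ids = [self.gene_ids[i] for i in gene_idx]
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            vals = vals[:, cell_idx]
            cell_ids = [self.cell_ids[i] for i in cell_idx]
        return CountMatrix(
            values=vals.copy(),
            gene_ids=gene_ids,
            cell_ids=cell_ids,
            unit=self.unit,
            gene_symbols=dict(self.gene_symbols),
        )


# ----------------------------------------------------------------------
# 10x-style triplet directories


def _dedupe(names: list[str]) -> tuple[list[str], dict[str, str]]:
    """Disambiguate duplicate names with an occurrence-counter suffix."""
    seen: dict[str, int] = {}
    out: list[str] = []
    symbols: dict[str, str] = {}
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            symbols[new] = name
        else:
            seen[name] = 0
            new = name
        out.append(new)
    return out, symbols


def _read_tsv_column(path: str, column: int | None = None) -> list[str]:
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if column is None:
                # prefer the symbol column of 10x genes/features files
                rows.append(fields[1] if len(fields) > 1 else fields[0])
            else:
                rows.append(fields[column])
    return rows


def read_10x_triplet(dir_path: str, unit: str = "umi") -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + genes/features.tsv + barcodes.tsv).

    MatrixMarket indices are 1-based per the standard; entries absent from
    the file are zero.
    """
    mtx_path = os.path.join(dir_path, "matrix.mtx")
    if not os.path.exists(mtx_path):
        raise MatrixInputError(f"missing matrix.mtx in {dir_path}")
    genes_path = os.path.join(dir_path, "genes.tsv")
    if not os.path.exists(genes_path):
        genes_path = os.path.join(dir_path, "features.tsv")
    if not os.path.exists(genes_path):
        raise MatrixInputError(f"missing genes.tsv/features.tsv in {dir_path}")
    barcodes_path = os.path.join(dir_path, "barcodes.tsv")
    if not os.path.exists(barcodes_path):
        raise MatrixInputError(f"missing barcodes.tsv in {dir_path}")

    try:
        mat = mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise MatrixFormatError(f"cannot parse {mtx_path}: {exc}") from exc
    genes = _read_tsv_column(genes_path)
    barcodes = _read_tsv_column(barcodes_path, column=0)
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise MatrixFormatError(
            f"matrix.mtx declares {n_genes} genes but gene file has {len(genes)} lines"
        )
    if len(barcodes) != n_cells:
        raise MatrixFormatError(
            f"matrix.mtx declares {n_cells} cells but barcode file has "
            f"{len(barcodes)} lines"
        )
    gene_ids, symbols = _dedupe(genes)
    return CountMatrix(
        values=sp.csr_matrix(mat),
        gene_ids=gene_ids,
        cell_ids=barcodes,
        unit=unit,
        gene_symbols=symbols,
    )


def write_10x_triplet(m: CountMatrix, dir_path: str) -> None:
    """Write ``m`` as matrix.mtx + genes.tsv + barcodes.tsv."""
    os.makedirs(dir_path, exist_ok=True)
    vals = m.values.tocoo()
    if m.unit in ("umi", "read_count"):
        vals = vals.astype(np.int64)
    mmwrite(os.path.join(dir_path, "matrix.mtx"), vals)
    with open(os.path.join(dir_path, "genes.tsv"), "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{m.gene_symbols.get(g, g)}\n")
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        for c in m.cell_ids:
            fh.write(f"{c}\n")


# ----------------------------------------------------------------------
# dense tables


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dense_csv(
    path: str,
    has_header: bool = True,
    genes_in_rows: bool = True,
    unit: str = "umi",
) -> CountMatrix:
    """Read a rectangular CSV/TSV expression table.

    With ``has_header`` the first row holds column ids and the first
    column row ids; otherwise ids are auto-generated.  ``genes_in_rows``
    controls orientation (genes in rows is the package convention).
    """
    if not os.path.exists(path):
        raise MatrixInputError(f"missing file {path}")
    sep = _sep_for(path)
    try:
        if has_header:
            df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        else:
            df = pd.read_csv(path, sep=sep, header=None)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"ragged or malformed table {path}: {exc}") from exc
    if df.isna().any().any():
        raise MatrixFormatError(f"ragged rows or missing values in {path}")
    values = df.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        raise ValueError(f"negative expression value in {path}")
    if has_header:
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        row_ids = [f"r{i}" for i in range(values.shape[0])]
        col_ids = [f"c{j}" for j in range(values.shape[1])]
    if genes_in_rows:
        gene_ids, cell_ids = row_ids, col_ids
    else:
        values = values.T
        gene_ids, cell_ids = col_ids, row_ids
        if not has_header:
            gene_ids = [f"r{i}" for i in range(values.shape[0])]
            cell_ids = [f"c{j}" for j in range(values.shape[1])]
    gene_ids, symbols = _dedupe(gene_ids)
    return CountMatrix(
        values=sp.csr_matrix(values),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        unit=unit,
        gene_symbols=symbols,
    )


def write_dense_csv(m: CountMatrix, path: str) -> None:
    df = pd.DataFrame(m.to_dense(), index=m.gene_ids, columns=m.cell_ids)
    df.to_csv(path, sep=_sep_for(path))


# ----------------------------------------------------------------------
# labels and assignments


def read_labels(path: str) -> dict[str, str]:
    """Read a two-column TSV mapping cell id -> class label."""
    if not os.path.exists(path):
        raise MatrixInputError(f"missing file {path}")
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            cell, label = fields
            if cell in mapping:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate cell id {cell!r}")
            mapping[cell] = label
    return mapping


def write_labels(mapping: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for cell, label in mapping.items():
            fh.write(f"{cell}\t{label}\n")


def write_assignment(cell_ids: list[str], labels, path: str) -> None:
    """Write (cell_id, cluster_id) pairs as TSV."""
    labels = np.asarray(labels)
    if len(cell_ids) != len(labels):
        raise ValueError("cell_ids and labels differ in length")
    with open(path, "w") as fh:
        for cell, lab in zip(cell_ids, labels):
            fh.write(f"{cell}\t{int(lab)}\n")


def read_assignment(path: str) -> dict[str, int]:
    return {cell: int(lab) for cell, lab in read_labels(path).items()}
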