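import numpy as np
import pytest
import scipy.sparse as sp

from sctfidf.io_matrix import CountMatrix
from sctfidf.synthetic import MixtureSpec, generate_mixture


def make_counts(values, unit="umi", gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    return CountMatrix(
        values=sp.csr_matrix(values),
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=cell_ids or [f"c{j}" for j in range(n_cells)],
        unit=unit,
    )


@pytest.fixture
def counts_factory():
    return make_counts


@pytest.fixture(scope="session")
def toy_mixture():
    """Dissimilar-tier 2-type mixture, 200 cells."""
    spec = MixtureSpec(seed=42, cells_per_type=(100, 100))
    return generate_mixture(spec)


@pytest.fixture(scope="session")
def toy_counts(toy_mixture):
    return toy_mixture[0]


@pytest.fixture(scope="session")
def toy_truth(toy_mixture):
    return toy_mixture[1]
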