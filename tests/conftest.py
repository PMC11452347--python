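"""Shared fixtures: small hand-built matrices and one session-scoped
synthetic dataset at the default study-like conditions."""

import numpy as np
import pytest
import scipy.sparse as sp

from vascomm import CountMatrix, synthetic


def make_counts(dense, gene_ids=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        gene_ids or [f"g{i}" for i in range(n_genes)],
        barcodes or [f"c{j}" for j in range(n_cells)],
    )


@pytest.fixture(scope="session")
def default_dataset():
    return synthetic.generate_dataset(synthetic.default_config(seed=11))


@pytest.fixture(scope="session")
def null_dataset():
    return synthetic.generate_null_dataset(synthetic.default_config(seed=11))
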