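import numpy as np
import pandas as pd
import pytest

from noisebench.simulate import GeneSpec, SimConfig
from noisebench.metrics import CountMatrix


@pytest.fixture
def basic_genes():
    return (
        GeneSpec("gA", 5.0, 4.0),
        GeneSpec("gB", 2.0, 10.0),
        GeneSpec("gC", 10.0, 1.0),
    )


@pytest.fixture
def basic_config(basic_genes):
    return SimConfig(
        genes=basic_genes,
        n_cells=200,
        n_replicates=2,
        extrinsic_coupling=0.0,
        amplification=2.0,
        seed=11,
    )


def toy_matrix(counts, conditions=None, replicates=None, gene_ids=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "condition": conditions or ["control"] * n_cells,
            "replicate": replicates or [1] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                       cell_meta=meta)


@pytest.fixture
def toy_matrix_factory():
    return toy_matrix
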