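import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sskit import preprocess as pp
from sskit import simulate as sim
from sskit.dataset import ExpressionDataset


def make_dataset(counts, gene_ids=None, normalized=None, **cell_cols):
    """Small ExpressionDataset straight from a dense array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(n_genes)]
    cell_table = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)], **cell_cols})
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_table=cell_table,
        gene_table=pd.DataFrame({"gene_id": gene_ids}),
    )
    if normalized is not None:
        ds.normalized = sp.csr_matrix(np.asarray(normalized, dtype=float))
    return ds


@pytest.fixture(scope="session")
def typed_dataset():
    """600 cells, 300 genes, 3 types with planted fold-8 markers, normalized."""
    types = [
        sim.CellTypeSpec("A", 0.4, marker_genes=range(0, 10), marker_fold=8.0, layer="L2/3"),
        sim.CellTypeSpec("B", 0.35, marker_genes=range(10, 20), marker_fold=8.0, layer="L5"),
        sim.CellTypeSpec("C", 0.25, marker_genes=range(20, 30), marker_fold=8.0, layer="L6"),
    ]
    spec = sim.PopulationSpec(cell_types=types, n_cells=600, n_genes=300, seed=11)
    data = sim.simulate_reference(spec)
    return pp.normalize_log(data)


@pytest.fixture(scope="session")
def null_dataset():
    """Homogeneous 500-cell population with a random two-condition split."""
    spec = sim.null_spec(n_cells=500, n_genes=400, seed=5)
    data = sim.simulate_conditions(spec, [], seed=7)
    return pp.normalize_log(data)
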