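import numpy as np
import pandas as pd
import pytest

from cellsignal import AnnotatedCellMatrix, SimulationSpec


def make_cells(counts, clusters, **meta_overrides):
    """Small AnnotatedCellMatrix with benign metadata unless overridden."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cluster": list(clusters),
            "mito_fraction": 0.01,
            "doublet": False,
            "cycle_phase": "G1",
            "leucocyte": False,
        },
        index=pd.Index(cell_ids),
    )
    for key, vals in meta_overrides.items():
        meta[key] = vals
    return AnnotatedCellMatrix(
        counts=counts,
        gene_ids=pd.Index([f"g{i}" for i in range(n_genes)]),
        cell_ids=pd.Index(cell_ids),
        meta=meta,
    )


@pytest.fixture
def tiny_cells():
    """3 genes x 4 cells, two clusters, everything passing QC."""
    counts = np.array([[5, 0, 2, 1], [3, 4, 0, 2], [0, 1, 1, 7]])
    return make_cells(counts, ["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        n_genes=300,
        n_celltypes=3,
        cells_per_type=60,
        marker_genes_per_type=20,
        seed=7,
    )
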