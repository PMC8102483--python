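import numpy as np
import pytest
import scipy.sparse as sp

from scskin.io import CountMatrix
from scskin.simulate import SimConfig, simulate_atlas


def make_cm(dense, genes=None, barcodes=None) -> CountMatrix:
    """CountMatrix from a dense genes x cells array with default names."""
    dense = np.asarray(dense)
    genes = genes or [f"G{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"C{j}" for j in range(dense.shape[1])]
    return CountMatrix(sp.csr_matrix(dense), genes, barcodes)


@pytest.fixture(scope="session")
def atlas():
    """Default synthetic atlas: K=8, ~100 cells/type, 30 markers at log2fc 3."""
    return simulate_atlas(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_atlas():
    """Compact 4-type atlas for fast clustering/marker tests."""
    cfg = SimConfig(
        n_types=4, genes=1000, marker_genes_per_type=30, de_genes_per_type=10,
        cells_per_type_per_donor={"control": 17, "disease": 17}, seed=2,
    )
    return simulate_atlas(cfg)


@pytest.fixture(scope="session")
def marker_table(atlas):
    """Filled MarkerTable on the default atlas using true type labels."""
    from scskin.markers import enrichment_scores, marker_fpr

    cm, _meta, truth = atlas
    return marker_fpr(cm, truth.true_type,
                      enrichment_scores(cm, truth.true_type),
                      n_perm=200, seed=1)


@pytest.fixture(scope="session")
def trained(atlas, marker_table):
    """(panel, model) trained on the default atlas with true labels."""
    from scskin.classifier import TrainConfig, build_panel, train

    cm, _meta, truth = atlas
    panel = build_panel(marker_table, k_per_cluster=30)
    model = train(cm, truth.true_type, panel, TrainConfig(seed=1))
    return panel, model
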