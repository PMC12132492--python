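import anndata as ad
import numpy as np
import pandas as pd
import pytest

from resistsig import io_prep, synthetic_data
from resistsig.io_prep import ExpressionMatrix
from resistsig.signatures import GeneSignature


def make_matrix(counts: np.ndarray, layer="counts", lines=None, clusters=None,
                treated=None) -> ExpressionMatrix:
    """Cells x genes array -> ExpressionMatrix with minimal metadata."""
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(
        {
            "cell_line": lines if lines is not None else ["L1"] * n_cells,
            "cluster": clusters if clusters is not None else ["c0"] * n_cells,
            "treated": treated if treated is not None else [True] * n_cells,
            "drug": "",
            "drug_class": "",
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    adata = ad.AnnData(
        counts.astype(float), obs=obs,
        var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
    )
    return ExpressionMatrix(adata, layer)


@pytest.fixture(scope="session")
def sim_small():
    """Small multi-line simulation shared across tests (2 lines, 6 clusters)."""
    m, truth = synthetic_data.simulate_cell_lines(
        n_lines=2, clusters_per_line=6, cells_per_cluster=80, n_genes=800,
        program_size=60, fold=4.0, seed=42,
    )
    return m, truth


@pytest.fixture(scope="session")
def sim_small_lognorm(sim_small):
    m, truth = sim_small
    return io_prep.lognormalize(m), truth


@pytest.fixture()
def toy_signature():
    return GeneSignature("toy", frozenset({"g0", "g1", "g2"}), "up")
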