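import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucleoshift import CountMatrix, generate_cohort
from nucleoshift.synthetic_cohort import (CellTypeSpec, CohortConfig,
                                          PlantedDEG, SubpopSpec)


def pool_cohort(matrices, truth) -> tuple[CountMatrix, pd.DataFrame]:
    """Concatenate per-sample matrices with prefixed barcodes (no QC)."""
    pooled = CountMatrix(
        sp.hstack([m.values for m in matrices]),
        matrices[0].gene_ids, matrices[0].gene_symbols,
        list(truth.cells.cell))
    return pooled, truth.cells


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 2 cells with entries {(0,0): 5, (2,1): 1}."""
    dense = np.array([[5, 0], [0, 0], [0, 1]])
    return CountMatrix(sp.csc_matrix(dense), ["g1", "g2", "g3"],
                       ["GENEA", "GENEB", "MT-CO1"], ["c1", "c2"])


@pytest.fixture(scope="session")
def six_type_cohort():
    """Small six-type case/control cohort with planted effects + truth."""
    cfg = CohortConfig(
        n_samples_case=4, n_samples_control=4, cells_per_sample=250,
        n_genes=1500,
        cell_types=[
            CellTypeSpec("excitatory_neuron", 0.35),
            CellTypeSpec("oligodendrocyte", 0.24),
            CellTypeSpec("astrocyte", 0.16),
            CellTypeSpec("inhibitory_neuron", 0.12),
            CellTypeSpec("microglia", 0.08),
            CellTypeSpec("endothelial", 0.05),
        ],
        subpops=[
            SubpopSpec("astrocyte", "a1", 0.35, 0.45,
                       deg_overexpression_log2fc=2.0),
            SubpopSpec("astrocyte", "a2", 0.40, 0.37),
            SubpopSpec("astrocyte", "a3", 0.25, 0.18,
                       deg_overexpression_log2fc=-2.0),
        ],
        planted_degs=[PlantedDEG("astrocyte", 20, 0.8),
                      PlantedDEG("astrocyte", 20, -0.8)],
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrices, samples, truth = generate_cohort(cfg)
    return cfg, matrices, samples, truth
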