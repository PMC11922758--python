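import numpy as np
import pandas as pd
import pytest

import hypoatlas as ha


@pytest.fixture(scope="session")
def small_hierarchy():
    """Two-level planted hierarchy (2x2 leaves, 100 cells each), well separated."""
    spec = ha.HierarchySpec(
        levels=(2, 2), cells_per_leaf=100, embedding_dim=10,
        separation=10.0, noise_sd=1.0, n_donors=4, n_batches=2, seed=42,
    )
    embedding, cells, truth = ha.simulate_hierarchy(spec)
    return spec, embedding, cells, truth


@pytest.fixture(scope="session")
def small_counts(small_hierarchy):
    _, _, cells, truth = small_hierarchy
    counts, markers = ha.simulate_counts(
        truth, cells, n_genes=120, markers_per_leaf=4, batch_effect_sd=0.3, seed=7
    )
    return counts, markers


def make_cell_table(**overrides):
    """One-row cell table with valid defaults, for QC boundary cases."""
    base = {
        "cell_id": "c0",
        "umi_count": 5000,
        "mito_fraction": 0.02,
        "donor_id": "d0",
        "sample_id": "s0",
        "batch_id": "b0",
        "doublet_flag": False,
    }
    base.update(overrides)
    return pd.DataFrame([base])
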