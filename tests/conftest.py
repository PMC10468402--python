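"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from contacttracing.expression import ExpressionDataset
from contacttracing.simulate import PlantedInteraction, TMEConfig, simulate_tme


@pytest.fixture(scope="session")
def tme():
    """Moderate synthetic TME with one planted condition-dependent interaction
    (15 effect genes, 10 receptor-correlated confounders), shared across tests."""
    cfg = TMEConfig(
        n_background_genes=120,
        n_cells_per_type_per_condition=300,
        interactions=(PlantedInteraction("LIG1", "Tumor", "RCPT1", "Macrophage",
                                         n_effect_genes=15, n_confounder_genes=10),),
    )
    ds, db, truth = simulate_tme(cfg, seed=11)
    return ds, db, truth


@pytest.fixture(scope="session")
def target_table(tme):
    from contacttracing.core import target_test
    ds, _, _ = tme
    return target_test(ds, "RCPT1", "Macrophage")


@pytest.fixture(scope="session")
def interaction_table(tme):
    from contacttracing.core import interaction_test
    ds, _, _ = tme
    return interaction_test(ds, "RCPT1", "Macrophage", ("CINhigh", "CINlow"))


@pytest.fixture()
def tiny_dataset():
    """Hand-built 6-cell, 4-gene dataset with subclusters and two conditions."""
    counts = np.array([
        [5, 0, 1, 2],
        [0, 3, 0, 1],
        [2, 2, 2, 2],
        [1, 0, 0, 4],
        [0, 1, 3, 0],
        [4, 4, 0, 1],
    ])
    obs = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(6)],
        "cell_type": ["A", "A", "A", "B", "B", "B"],
        "condition": ["hi", "lo", "hi", "lo", "hi", "lo"],
        "subcluster": ["s0", "s0", "s1", "s0", "s1", "s1"],
        "sample_id": "s",
    })
    return ExpressionDataset.from_counts(sp.csr_matrix(counts),
                                         ["g1", "g2", "g3", "g4"], obs)
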