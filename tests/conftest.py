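import numpy as np
import pandas as pd
import pytest

from polytrans.sc import CellMatrix
from polytrans.simulate import SimConfig, simulate_sc_experiment


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(seed=11, n_genes=200, n_cells_per_group=80,
                     depth_mean=3000, dispersion=0.1)


@pytest.fixture(scope="session")
def small_sc_dataset(small_sim_config):
    return simulate_sc_experiment(small_sim_config)


@pytest.fixture()
def tiny_cell_matrix():
    """Hand-built 6-cell x 4-gene matrix with controllable metadata."""
    counts = np.array([
        [10, 0, 5, 1],
        [8, 1, 4, 0],
        [12, 0, 6, 2],
        [1, 9, 0, 3],
        [0, 11, 1, 2],
        [2, 8, 0, 4],
    ])
    cells = pd.DataFrame({
        "group": ["A", "A", "A", "B", "B", "B"],
        "cell_type": ["t0", "t0", "t1", "t0", "t1", "t1"],
        "umi": counts.sum(axis=1),
        "n_genes": (counts > 0).sum(axis=1),
        "mito_frac": [0.01, 0.02, 0.03, 0.01, 0.02, 0.03],
    }, index=[f"c{i}" for i in range(6)])
    return CellMatrix(counts, cells, pd.Index(["g0", "g1", "g2", "g3"]))
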