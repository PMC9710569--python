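import numpy as np
import pandas as pd
import pytest

from sparcle import (
    SimConfig,
    SpotTable,
    build_count_matrix,
    simulate_fov,
)
from sparcle.core_io import STATUS_DANGLING


def make_spot_table(rows, panel=None):
    """rows: iterable of (spot_id, gene, x, y)."""
    df = pd.DataFrame(rows, columns=["spot_id", "gene", "x", "y"])
    df["status"] = STATUS_DANGLING
    df["cell_id"] = -1
    df["iteration"] = 0
    if panel is None:
        panel = sorted(df["gene"].unique())
    return SpotTable(df, list(panel))


@pytest.fixture(scope="session")
def small_sim():
    """A small FoV that exercises the whole pipeline quickly."""
    cfg = SimConfig(n_cells=30, n_genes=40, n_clusters=3, field_size=(300, 300),
                    counts_per_cell_mean=200, seed=7)
    spots, seg, truth = simulate_fov(cfg)
    return cfg, spots, seg, truth


@pytest.fixture
def small_sim_fresh(small_sim):
    """Copy of the small FoV safe to mutate, with a fresh count matrix."""
    cfg, spots, seg, truth = small_sim
    spots = spots.copy()
    matrix = build_count_matrix(spots, seg)
    return cfg, spots, seg, truth, matrix


@pytest.fixture
def rng():
    """Fresh fixed-seed generator per test, so tests are order-independent."""
    return np.random.default_rng(42)
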