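import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import neurocmap as nc


@pytest.fixture(scope="session")
def small_screen():
    """A compact planted screen shared by unit tests (3 cells x 12 compounds)."""
    cfg = nc.ScreenConfig(
        n_cell_lines=3,
        n_compounds=12,
        n_replicates=3,
        n_genes=120,
        invariant_per_level=4,
        vehicle_wells_per_plate=4,
    )
    return nc.simulate_screen(cfg, seed=11)


@pytest.fixture(scope="session")
def small_processed(small_screen):
    return nc.process_screen(
        small_screen.beads, small_screen.samples, small_screen.panel
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 samples with 2 row-meta and 3 col-meta fields."""
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    row_meta = pd.DataFrame(
        {"gene_symbol": ["A", "B", "C"], "invariant_level": ["0", "0", "1"]},
        index=values.index,
    )
    col_meta = pd.DataFrame(
        {
            "plate_id": ["P1"] * 4,
            "pert_id": ["X", "X", "DMSO", "DMSO"],
            "cell_id": ["CL1"] * 4,
        },
        index=values.columns,
    )
    return nc.ExpressionMatrix(values=values, row_meta=row_meta, col_meta=col_meta, level=3)
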