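import numpy as np
import pandas as pd
import pytest

from stagewave.io_formats import CountMatrix
from stagewave.stage_grouping import AgeGroupScheme
from stagewave.synthetic_data import SimulationConfig, generate_counts

LIBS = ["0dpp", "4dpp", "8dpp", "12dpp", "16dpp"]


@pytest.fixture(scope="session")
def default_sim():
    """One desk-scale simulated dataset shared across tests (fixed seed)."""
    cfg = SimulationConfig(n_contigs=5000, library_depths=(50_000,) * 5, seed=11)
    counts, lengths, annotations, truth = generate_counts(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "lengths": lengths,
        "annotations": annotations,
        "truth": truth,
    }


@pytest.fixture
def toy_counts():
    """Small hand-built matrix with known totals."""
    df = pd.DataFrame(
        {
            "0dpp": [10, 0, 5, 100],
            "4dpp": [10, 0, 5, 100],
            "8dpp": [0, 20, 5, 100],
            "12dpp": [0, 0, 5, 100],
            "16dpp": [0, 0, 5, 100],
        },
        index=["a", "b", "c", "d"],
    )
    return CountMatrix(df)


@pytest.fixture
def three_group_scheme():
    """The {0+4, 8, 12+16} grouping over one library per age."""
    return AgeGroupScheme.from_ages([(0, 4), (8,), (12, 16)], LIBS)


def random_count_matrix(rng, n=50, depths=(1000, 1200, 900, 1100, 1000)):
    data = {
        lab: rng.integers(0, 40, size=n) for lab in LIBS
    }
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(n)])
    # force positive depths
    df.iloc[0] += 1
    return CountMatrix(df)
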