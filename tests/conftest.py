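import numpy as np
import pandas as pd
import pytest

from exodep import SimulationConfig, SpectralCountMatrix, make_group_map, simulate_counts


@pytest.fixture
def tiny_matrix() -> SpectralCountMatrix:
    """4 proteins x 5 samples (2 in A, 3 in B), hand-checkable counts."""
    values = pd.DataFrame(
        {
            "A1": [10, 0, 4, 2],
            "A2": [8, 0, 6, 4],
            "B1": [2, 5, 4, 6],
            "B2": [4, 7, 6, 2],
            "B3": [3, 6, 2, 4],
        },
        index=pd.Index(["P1", "P2", "P3", "P4"], name="protein_id"),
    )
    return SpectralCountMatrix(values, make_group_map(["A1", "A2"], ["B1", "B2", "B3"]))


@pytest.fixture(scope="session")
def default_study():
    """One study at the default design (506 proteins, 48/41 uniques, 4 vs 7)."""
    return simulate_counts(SimulationConfig(seed=1))


@pytest.fixture
def null_config():
    return SimulationConfig(n_up=0, n_down=0, n_unique_a=0, n_unique_b=0, seed=7)
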