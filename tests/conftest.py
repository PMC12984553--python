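import numpy as np
import pandas as pd
import pytest

from rfecomm import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Three-group synthetic dataset, small enough for fast unit tests."""
    cfg = SimulationConfig(
        group_sizes={"A": 4, "B": 4, "C": 3},
        n_otus=60,
        n_planted_markers_per_group=3,
        depth_range=(1000, 4000),
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-design-sized dataset (45 species, 135 samples)."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture()
def toy_table():
    """Tiny hand-written OTU table: 4 samples x 3 OTUs, two groups."""
    return pd.DataFrame(
        [[4, 6, 0], [6, 4, 0], [0, 2, 8], [0, 4, 6]],
        index=["a1", "a2", "b1", "b2"],
        columns=["OTU1", "OTU2", "OTU3"],
    )


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "species": ["spA", "spA", "spB", "spB"],
            "group": ["A", "A", "B", "B"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
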