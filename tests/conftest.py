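import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from gutscape.data_model import FeatureTable
from gutscape.synthetic import SimulationConfig, simulate_study


@pytest.fixture
def toy_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table() -> FeatureTable:
    counts = np.array([[5, 0, 2],
                       [3, 2, 0],
                       [0, 2, 2]])
    return FeatureTable(counts, ["A", "B", "C"], ["s1", "s2", "s3"])


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    rows = {
        "s1": dict(site="siteA", province="p1", latitude=30.0, longitude=100.0,
                   elevation=1200.0, annual_mean_temperature=12.0,
                   annual_precipitation=600.0, population_density=50.0,
                   human_footprint=12.0),
        "s2": dict(site="siteA", province="p1", latitude=30.0, longitude=100.0,
                   elevation=1200.0, annual_mean_temperature=12.0,
                   annual_precipitation=600.0, population_density=50.0,
                   human_footprint=12.0),
        "s3": dict(site="siteB", province="p2", latitude=40.0, longitude=110.0,
                   elevation=500.0, annual_mean_temperature=8.0,
                   annual_precipitation=400.0, population_density=200.0,
                   human_footprint=25.0),
    }
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample_id"
    return meta


@pytest.fixture(scope="session")
def small_drift_study():
    """A small neutral-drift simulated study reused across tests."""
    cfg = SimulationConfig(n_taxa=60, n_sites=4, samples_per_site=(4, 4),
                           depth=800, regime="neutral_drift", seed=42)
    return simulate_study(cfg)
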