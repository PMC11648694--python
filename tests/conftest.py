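import numpy as np
import pandas as pd
import pytest
import skbio

from coregrad import FeatureTable, SimulationConfig, simulate_dataset
from coregrad.data_model import RANKS


@pytest.fixture
def four_leaf_tree() -> skbio.TreeNode:
    return skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def small_table() -> FeatureTable:
    return FeatureTable(
        pd.DataFrame(
            {"s1": [3, 0, 7], "s2": [1, 5, 2]},
            index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
        )
    )


def make_taxonomy(entries: dict[str, list[str]]) -> pd.DataFrame:
    """Build a taxonomy frame from {feature: partial lineage} (right-padded)."""
    rows = {f: lin + [""] * (len(RANKS) - len(lin)) for f, lin in entries.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "feature_id"
    return df


@pytest.fixture
def small_taxonomy() -> pd.DataFrame:
    return make_taxonomy(
        {
            "f1": ["Bacteria", "Proteobacteria", "Alpha", "Acetobacterales",
                   "Acetobacteraceae", "Acetobacter", "A. sp1"],
            "f2": ["Bacteria", "Proteobacteria", "Alpha", "Acetobacterales",
                   "Acetobacteraceae", "Acetobacter", "A. sp2"],
            "f3": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                   "Lactobacillaceae", "Lactobacillus", "L. sp1"],
        }
    )


def random_table(rng: np.random.Generator, n_features=12, n_samples=6, depth=300) -> FeatureTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_features)), size=n_samples).T
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=pd.Index([f"f{i}" for i in range(n_features)], name="feature_id"),
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but full two-transect simulated dataset, shared across tests."""
    config = SimulationConfig(
        n_sites_lat=3,
        n_sites_alt=3,
        replicates_per_stage_site=2,
        n_features=60,
        n_contaminants=4,
        depth_fly=3000,
        depth_pulp=800,
        seed=42,
    )
    return config, simulate_dataset(config)
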