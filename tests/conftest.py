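import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microstab.simulate import SimulationSpec, default_profiles, simulate_dataset
from microstab.tabletools import (
    FeatureTable,
    Lineage,
    SampleMetadata,
    TaxonomyMap,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    """3 samples x 4 taxa with known totals."""
    return FeatureTable(
        pd.DataFrame(
            [[5, 0, 1, 4], [2, 2, 0, 0], [0, 0, 0, 9]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3", "t4"],
        )
    )


@pytest.fixture
def small_taxonomy():
    return TaxonomyMap(
        {
            "t1": Lineage("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                          "Clostridiaceae", ""),
            "t2": Lineage("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                          "Clostridiaceae", ""),
            "t3": Lineage("Bacteria", "Cyanobacteria", "", "Chloroplast", "", ""),
            "t4": Lineage("Bacteria", "Bacteroidota", "Bacteroidia",
                          "Bacteroidales", "", ""),
        }
    )


@pytest.fixture
def small_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "species": ["lion", "lion", "zebra"],
                "group": ["Feloidea", "Feloidea", "Perissodactyla"],
                "diet": ["carnivore", "carnivore", "herbivore"],
                "zoo": ["z1", "z2", "z1"],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Small synthetic dataset shared by integration-style tests."""
    spec = SimulationSpec(
        profiles=default_profiles(),
        species_per_group=2,
        samples_per_species=8,
        seed=42,
    )
    return simulate_dataset(spec)


def random_feature_table(rng, n_samples, n_taxa, max_count=50):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
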