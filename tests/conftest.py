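import numpy as np
import pandas as pd
import pytest

from oxygrad.io import RANKS, CountTable, SampleMetadata, TaxonomyTable
from oxygrad.coda import impute_zeros
from oxygrad.simulate import ArchetypeSpec, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_table():
    """4 OTUs x 3 samples with a singleton and a shallow sample."""
    counts = pd.DataFrame(
        {
            "s1": [500, 400, 99, 1],
            "s2": [600, 300, 100, 0],
            "s3": [700, 200, 99, 0],
        },
        index=["otu1", "otu2", "otu3", "otu4"],
    )
    return CountTable(counts)


@pytest.fixture
def random_table(rng):
    """20 OTUs x 12 samples of Poisson counts with scattered zeros."""
    counts = rng.poisson(40, size=(20, 12))
    counts[rng.random(counts.shape) < 0.15] = 0
    counts[:, counts.sum(axis=0) == 0] += 1  # no all-zero samples
    df = pd.DataFrame(
        counts,
        index=[f"otu{i:02d}" for i in range(20)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
    return CountTable(df.astype(np.int64))


@pytest.fixture
def random_composition(random_table):
    return impute_zeros(random_table)


@pytest.fixture
def toy_taxonomy():
    lineages = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P2", "P2"],
            "class": ["A", "A", "B", "B"],
            "order": ["A1", "A2", "unassigned", "B1"],
            "family": ["unassigned"] * 4,
        },
        index=["otu1", "otu2", "otu3", "otu4"],
    )
    return TaxonomyTable(lineages[list(RANKS)])


@pytest.fixture
def small_sim_config():
    """Desk-scale-but-fast generator settings used across tests."""
    design = {
        "Thresholdia": [ArchetypeSpec("threshold_responder", n_otus=20, effect_size=2.0)],
        "Stochastia": [ArchetypeSpec("non_responder", n_otus=20, within_category_sd=1.5)],
        "Backgroundia": [ArchetypeSpec("uniform_noise", n_otus=20)],
    }
    return SimulationConfig(n_cores=6, depths_per_core=12, class_design=design)


@pytest.fixture(scope="session")
def default_dataset():
    """One full default-scale dataset shared by read-only tests."""
    return simulate_dataset(SimulationConfig(), seed=11)
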