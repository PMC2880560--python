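from pathlib import Path

import pandas as pd
import pytest

from envfam.synthetic_data import WorldConfig, generate_world

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_stats() -> pd.DataFrame:
    """Published (g, n, G, N) counts with their printed Ov/Ex/Es triples."""
    return pd.read_csv(DATA_DIR / "reference_family_stats.tsv", sep="\t")


@pytest.fixture(scope="session")
def tiny_world():
    """A very small world for fast unit tests of downstream stages."""
    return generate_world(
        WorldConfig(
            n_related_genomes=5,
            n_unrelated_genomes=8,
            proteins_per_genome=6,
            n_metagenome_orfs=120,
            n_planted_families=6,
            frac_env_specific=0.5,
            frac_known=0.0,
            rng_seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_world():
    """The default-parameter world used by the recovery benchmarks."""
    return generate_world(WorldConfig(rng_seed=1))
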