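import numpy as np
import pandas as pd
import pytest

from chromage import genome_io
from chromage.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome that keeps unit tests fast."""
    return SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length_bp=2_000_000,
        hic_bin_size=50_000,
        n_genes=60,
        fragment_length_mean=2_000,
        flip_patterns=[("active_promoter", "polycomb", 5),
                       ("active_promoter", "bivalent", 5),
                       ("polycomb", "active_regulatory", 5)],
        n_interactions=120,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def toy_genome():
    return genome_io.Genome({"chr1": 100_000, "chr2": 50_000})


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    start = rng.integers(0, max_pos, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {"chrom": rng.choice(chroms, size=n), "start": start, "end": start + length,
         "name": [f"iv{i}" for i in range(n)]}
    )
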