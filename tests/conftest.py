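import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crowmeth.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study, shared across the suite."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast bundle for I/O and round-trip tests."""
    cfg = SimConfig(
        chromosomes=[type(SimConfig().chromosomes[0])("chr18", 400_000),
                     type(SimConfig().chromosomes[0])("chr1", 300_000)],
        focal_region=("chr18", 100_000, 250_000),
        n_genes=12, n_repeats=20, n_snps=800, n_cpgs_assayed=1500,
        n_age_effects=30, n_sex_effects=20, n_taxon_both=15,
        n_taxon_comgar=5, n_taxon_hybzon=5, n_year_effects=5, seed=11)
    return simulate_bundle(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
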