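import numpy as np
import pytest

from stressweave.genome import Annotation, Gene
from stressweave.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact study design: fast to simulate, still exercises every stage."""
    return SimulationConfig(
        seed=11, n_coding=40, n_ncrna=20, chrom_length=40_000,
        pair_geometry_counts=(10, 4, 4), n_planted_extensions=4,
        n_planted_modules=1, module_family_size=15, n_repression_pairs=5,
        n_families=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, with_coverage=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_annotation() -> Annotation:
    """Hand-built two-strand annotation on a 3 kb chromosome."""
    genes = [
        Gene("g_plus", "chr1", 100, 600, "+", "coding", cds_start=150, cds_end=500),
        Gene("g_minus", "chr1", 900, 1400, "-", "coding", cds_start=1000, cds_end=1300),
        Gene("nc_anti", "chr1", 400, 800, "-", "ncRNA"),
        Gene("g_far", "chr1", 2000, 2500, "+", "coding", cds_start=2100, cds_end=2400),
    ]
    return Annotation(genes, {"chr1": 3000})
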