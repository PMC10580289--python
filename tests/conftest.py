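import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from autozyg import synthdata as sd
from autozyg.genome import GeneticMap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# reduced synthetic genome used throughout the unit tests: 6 x 150 Mb
# chromosomes at 1 cM/Mb with ~33 kb marker spacing (dense enough for the
# 50-SNP / 1.5-Mb / 50-kb-per-SNP segment filters)
TEST_CHROMS = 6
TEST_CHROM_BP = 150_000_000
TEST_SITES_PER_CHROM = 4500


@pytest.fixture(scope="session")
def test_gmap() -> GeneticMap:
    return GeneticMap.uniform(TEST_CHROMS, TEST_CHROM_BP, 1.0)


@pytest.fixture(scope="session")
def panel(test_gmap) -> sd.FounderPanel:
    return sd.generate_founders(
        50,
        TEST_SITES_PER_CHROM,
        TEST_CHROMS,
        chrom_length_bp=TEST_CHROM_BP,
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def fc_offspring(panel):
    """Genotypes + truth for 80 first-cousin offspring (shared across
    tests to amortize the gene-dropping cost)."""
    return sd.simulate_union_offspring(panel, "first_cousin_1g", 80, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
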