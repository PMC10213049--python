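import numpy as np
import pytest

from straindyad import CohortConfig, generate_ancestral_genome, simulate_cohort


@pytest.fixture(scope="session")
def genome_100k():
    return generate_ancestral_genome(100_000, 0.5941, 1, genome_id="ref100k")


@pytest.fixture(scope="session")
def genome_50k():
    return generate_ancestral_genome(50_000, 0.5941, 2, genome_id="ref50k")


@pytest.fixture(scope="session")
def small_cohort():
    """Six dyads, one species: enough lineage structure for every stage."""
    return simulate_cohort(CohortConfig(n_dyads=6, species=("sp1",), seed=3))


def hamming(a, b) -> int:
    """Brute-force Hamming distance between two genomes (test oracle)."""
    return int(np.count_nonzero(a.codes != b.codes))
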