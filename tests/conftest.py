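import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from enddiff.synthetic import generate_genome, plant_genes


@pytest.fixture(scope="session")
def small_genome_genes():
    """A 2x30-kb genome with 12 clean genes on alternating strands."""
    genome = generate_genome(2, [30_000, 30_000], gc=0.38, seed=11)
    genome, genes = plant_genes(genome, 12, orf_len_range=(300, 900),
                                spacing_min=1200, seed=12)
    return genome, genes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
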