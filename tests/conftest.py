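import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from btmap.genome import build_genome_map
from btmap.simulate import BC1, BC2, make_backcross


@pytest.fixture(scope="session")
def tiny_gmap():
    """Two chromosomes, 10 markers each, 1 Mb / 50 cM."""
    return build_genome_map(
        n_chromosomes=2, physical_lengths=1_000_000, genetic_lengths=50.0,
        marker_spacing=100_000,
    )


@pytest.fixture(scope="session")
def tiny_locus(tiny_gmap):
    """Causal marker: middle of chr1."""
    return ("chr1", 500_000)


@pytest.fixture(scope="session")
def bc1_pop(tiny_gmap, tiny_locus):
    return make_backcross(BC1, tiny_gmap, 400, seed=11, r2_locus=tiny_locus)


@pytest.fixture(scope="session")
def bc2_pop(tiny_gmap, tiny_locus):
    return make_backcross(BC2, tiny_gmap, 400, seed=12, r2_locus=tiny_locus)
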