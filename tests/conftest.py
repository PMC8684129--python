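import numpy as np
import pytest
from hypothesis import settings

from chromstrat.simulate import SyntheticCohortSpec, generate_cohort

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


SMALL_SPEC = dict(
    n_tumors_per_group=(6, 6, 6),
    n_regions=150,
    n_signature_per_group=15,
    genome_length=150_000,
    chrom_count=2,
    region_length=300,
    n_genes=24,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny full cohort (genome, tracks, peaks included) for fast tests."""
    return generate_cohort(SyntheticCohortSpec(seed=11, **SMALL_SPEC))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Matrix-level cohort with no accessibility noise (exact planted means)."""
    return generate_cohort(
        SyntheticCohortSpec(seed=7, noise_sd=0.0, **SMALL_SPEC),
        with_genome=False,
        with_tracks=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
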