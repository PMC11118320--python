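import numpy as np
import pytest

from epistate import GenomeLayout, bivalency_counts, split_biv_groups
from epistate.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_groups(default_cohort):
    profile = bivalency_counts(default_cohort.truth_states)
    return split_biv_groups(profile).groups


@pytest.fixture(scope="session")
def small_spec():
    """A miniature spec for fast emission / round-trip checks."""
    return CohortSpec(
        seed=3,
        n_samples=6,
        n_genes=80,
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
        n_regions=40,
        n_group_specific=5,
        n_islands=8,
        n_background_cpgs=100,
        n_switch_genes=5,
        biv_pool_fraction=0.5,
        biv_low_range=(5, 10),
        biv_high_range=(25, 35),
    )


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chrT": 100_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
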