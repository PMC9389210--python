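import pytest

from cosag.synthetic_data import SimulationConfig, simulate_ancestor, simulate_cohort


@pytest.fixture(scope="session")
def ancestor_100k():
    return simulate_ancestor(100_000, 0.5, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """3 strains x 3 SAGs at 100 kb, completeness 0.7, no reads."""
    cfg = SimulationConfig(
        n_strains=3, sags_per_strain=3, target_completeness=0.7, mean_depth=0.0, seed=5
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_records(small_cohort):
    from cosag.similarity import pairwise_similarity

    return pairwise_similarity(small_cohort.assemblies, small_cohort.markers)


@pytest.fixture(scope="session")
def read_cohort():
    """Single strain, 3 SAGs with reads, chimeras and host contamination."""
    cfg = SimulationConfig(
        genome_length=50_000,
        n_strains=1,
        sags_per_strain=3,
        target_completeness=0.85,
        mean_depth=8.0,
        chimera_rate=0.05,
        error_rate=0.005,
        host_decoy_rate=0.1,
        seed=11,
    )
    return simulate_cohort(cfg)
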