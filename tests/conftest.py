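import pytest
from hypothesis import settings

from sbtrace import simulate, trimming

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome():
    return simulate.generate_genome(2, [50000, 40000], seed=11)


@pytest.fixture(scope="session")
def population(genome):
    return simulate.simulate_clonal_population(genome, 25, alpha=1.0, seed=12)


@pytest.fixture(scope="session")
def clean_library(population, genome):
    """Error-free, duplicate-free library: the exact-recovery oracle."""
    return simulate.simulate_trace_library(
        population, genome, 800, dup_rate=0.0, error_rate=0.0, seed=13
    )


@pytest.fixture(scope="session")
def dup_library(population, genome):
    return simulate.simulate_trace_library(
        population, genome, 800, dup_rate=0.2, error_rate=0.0, seed=14
    )


def pairs_of(library):
    return [
        trimming.ReadPair(name, r1, q1, r2, q2)
        for name, r1, q1, r2, q2 in library.reads
    ]


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    truth = simulate.simulate_variant_cohort(
        5, 3, n_shared_per_sample=70, n_private_per_sample=30,
        indel_fraction=0.1, seed=15, out_dir=out,
    )
    return truth
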