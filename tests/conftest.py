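import numpy as np
import pytest

from diffmnase.array_simulator import build_template
from diffmnase.synthetic_data import Domain, GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def default_template():
    return build_template(50, 150, 30, 5)


@pytest.fixture(scope="session")
def small_genome():
    """200 kb single-chromosome genome at uniform GC 0.5."""
    spec = GenomeSpec(chromosomes=[("chr1", 200_000)], seed=11)
    genome, dyads = generate_genome(spec)
    return spec, genome, dyads


@pytest.fixture(scope="session")
def periodic_genome():
    spec = GenomeSpec(
        chromosomes=[("chrP", 400_000)], periodic_positioning=True, seed=7
    )
    genome, dyads = generate_genome(spec)
    return spec, genome, dyads


@pytest.fixture(scope="session")
def biased_pipeline_run():
    """Full pipeline on the 5-Mb GC-biased genome with 50 planted sites.

    Session-scoped: shared by the end-to-end acceptance tests.
    """
    from diffmnase.pipeline import biased_genome_spec, run_pipeline

    return run_pipeline(
        biased_genome_spec(seed=1),
        n_fragments=2_000_000,
        window_sizes=(5_000, 25_000, 100_000, 500_000, 1_000_000),
        seed=1,
    )


def rng(seed=0):
    return np.random.default_rng(seed)
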