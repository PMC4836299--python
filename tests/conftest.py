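import numpy as np
import pytest

from orthocombine.synthetic_fixtures import ToyGenome, build_tiny_bundle


@pytest.fixture(scope="session")
def tiny_bundle():
    """(genome, truth, calls_a, calls_b, track_a, track_b) for the 12-site
    hand-classified case."""
    return build_tiny_bundle(seed=0)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(42)
    return ToyGenome.generate(rng, n_contigs=2, exons_per_contig=30, exon_length=150, spacing=80)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
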