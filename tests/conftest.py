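import numpy as np
import pytest

from adnapipe.synth_genomes import estimate_substitution_stats, simulate_genome_pair


@pytest.fixture(scope="session")
def small_pair():
    """A 20-kb genome pair at the default human/chimp-like calibration."""
    return simulate_genome_pair(20_000, 0.012, 5e-4, seed=7)


@pytest.fixture(scope="session")
def small_pair_stats(small_pair):
    _ga, _gb, aln = small_pair
    return estimate_substitution_stats(aln)


@pytest.fixture(scope="session")
def identical_pair():
    """A pair with zero divergence: two identical genomes, one block."""
    return simulate_genome_pair(2_000, 0.0, 0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
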