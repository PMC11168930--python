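import numpy as np
import pytest

from palindromekit import synth
from palindromekit.seqio import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_intervals():
    """Factory for random non-degenerate intervals on one chromosome."""

    def make(rng, n, chrom="c", total=10_000, max_len=800):
        out = []
        for _ in range(n):
            s = int(rng.integers(0, total - max_len))
            e = s + int(rng.integers(1, max_len))
            out.append(GenomicInterval(chrom, s, e))
        return out

    return make


@pytest.fixture(scope="session")
def small_palindrome_fixture():
    """One 300-kb chromosome with a single planted palindrome (shared
    across tests to amortize detection cost)."""
    spec = synth.SynthSpec(chrom_name="chrT", chrom_length=300_000, seed=11)
    spec.palindromes = [
        synth.PlantedPalindrome(position=100_000, arm_len=10_000,
                                spacer_len=30_000, divergence=0.01)
    ]
    record, track, truth = synth.generate_chromosome(spec)
    return spec, record, track, truth
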