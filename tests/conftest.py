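import numpy as np
import pytest

from hireschip import Fragment, FragmentSet, GenomeInfo, MotifSite


@pytest.fixture
def genome():
    return GenomeInfo({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def tiny_genome():
    return GenomeInfo({"chr1": 10})


def make_fragset(intervals, n_total=None):
    """Build a FragmentSet from (chrom, start, end) tuples."""
    frags = [Fragment(c, s, e) for c, s, e in intervals]
    return FragmentSet(frags, n_total_mapped=n_total)


def random_fragset(rng, genome, n, max_len=200):
    chroms = list(genome.chrom_lengths)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        L = int(rng.integers(1, max_len + 1))
        s = int(rng.integers(0, genome.length_of(c) - L))
        out.append((c, s, s + L))
    return make_fragset(out)


@pytest.fixture
def site19():
    """A 19-bp site at [100, 119); center 109."""
    return MotifSite("chr1", 100, 119, name="m0", strand="+")
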