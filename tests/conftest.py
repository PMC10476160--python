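import numpy as np
import pytest

from wgdkit.io import GeneTable, HomologyHit


@pytest.fixture
def rng():
    return np.random.default_rng(20230711)


@pytest.fixture
def small_table():
    """One genome, two chromosomes, contiguous gene order."""
    rows = []
    for chrom, n in (("c1", 8), ("c2", 6)):
        for i in range(n):
            rows.append((chrom, i * 100, i * 100 + 90, 1, f"{chrom}_g{i}"))
    return GeneTable.from_records("G", rows)


def make_hits(pairs, bitscore=200.0, evalue=1e-30):
    """Helper: HomologyHit list from (query, subject) or full tuples."""
    out = []
    for p in pairs:
        if len(p) == 2:
            q, s = p
            out.append(HomologyHit(q, s, 90.0, bitscore, evalue))
        else:
            q, s, bs, ev = p
            out.append(HomologyHit(q, s, 90.0, bs, ev))
    return out
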