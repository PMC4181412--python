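import numpy as np
import pytest

from clonaltree.pileup_io import BaseCall, PileupColumn


def make_column(pos=100, ref="A", alt="T", n_ref=100, n_alt=0,
                quality=35, alt_quality=None, chrom="chr1",
                read_pos_ref=40, read_pos_alt=40, alt_forward=None,
                alt_read_starts=None):
    """Build a pileup column with prescribed reference/variant calls.

    Reference calls alternate strands; variant strands default to
    alternating as well unless ``alt_forward`` (list of bools) is given.
    """
    calls = []
    for i in range(n_ref):
        calls.append(BaseCall(ref, quality, "+" if i % 2 == 0 else "-",
                              read_pos_ref, pos - read_pos_ref + 1 + (i % 7)))
    alt_quality = alt_quality if alt_quality is not None else quality
    for i in range(n_alt):
        if alt_forward is not None:
            strand = "+" if alt_forward[i] else "-"
        else:
            strand = "+" if i % 2 == 0 else "-"
        start = (alt_read_starts[i] if alt_read_starts is not None
                 else pos - read_pos_alt + 1 + (i % 11))
        calls.append(BaseCall(alt, alt_quality, strand, read_pos_alt, start))
    return PileupColumn.from_calls(chrom, pos, ref, calls)


def make_region(n_sites=25, start=100, coverage=200, ref="A",
                variant_at=None, n_alt=0, **kwargs):
    """A run of adjacent all-reference columns, optionally one variant."""
    cols = []
    for i in range(n_sites):
        pos = start + i
        if variant_at is not None and pos == variant_at:
            cols.append(make_column(pos=pos, ref=ref, n_ref=coverage - n_alt,
                                    n_alt=n_alt, **kwargs))
        else:
            cols.append(make_column(pos=pos, ref=ref, n_ref=coverage))
    return cols


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def draw_cluster_profile(rng, freqs, size, n_range, chrom="cX"):
    """Mutations drawn around planted frequencies, each consistent with
    its own cluster (CI covers the planted value), as in a resolved
    published mutation table."""
    from clonaltree.calling import SomaticMutation
    from clonaltree.clustering import frequency_ci

    out = []
    for j, f in enumerate(freqs):
        made = 0
        while made < size:
            n = int(rng.integers(*n_range))
            r = int(rng.binomial(n, f))
            if r < 1:
                continue
            lo, hi = frequency_ci(r, n)
            if not (lo <= f <= hi):
                continue
            out.append(SomaticMutation(
                chrom=chrom, pos=j * 10000 + made, ref_base="A",
                alt_base="T", r=r, n=n, frequency=r / n))
            made += 1
    return out
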