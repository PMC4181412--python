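import math

import numpy as np
import pytest
from scipy import stats

from clonaltree.calling import (CallerConfig, SomaticMutation, call_variants,
                                chernoff_bound, chernoff_pvalue,
                                compute_mismatch_profile,
                                determine_usable_window, flanking_pvalue,
                                prefilter_site, select_gold_set,
                                subtract_germline, WindowDetectionError)
from clonaltree.pileup_io import BaseCall, PileupColumn

from conftest import make_column, make_region


# ---------------------------------------------------------------------------
# Chernoff bound

def test_chernoff_below_mean_is_one():
    assert chernoff_pvalue([30] * 1000, 1) == 1.0
    assert chernoff_pvalue([30] * 1000, 0) == 1.0


@pytest.mark.parametrize("quals, r, expected", [
    # n=1000 at Q30: mu=1, delta=9 -> e^9 / 10^10
    ([30] * 1000, 10, math.exp(9) / 10 ** 10),
    # n=100 at Q20: mu=1, delta=4 -> e^4 / 5^5
    ([20] * 100, 5, math.exp(4) / 5 ** 5),
])
def test_chernoff_closed_form(quals, r, expected):
    res = chernoff_bound(quals, r)
    assert res.mu == pytest.approx(1.0)
    assert res.p_bound == pytest.approx(expected, rel=1e-12)


def test_chernoff_r_not_exceeding_mu():
    # the bound is vacuous (1.0) whenever the observed count does not
    # exceed the expected error count
    res = chernoff_bound([60] * 10, 0)
    assert res.p_bound == 1.0
    assert chernoff_pvalue([10] * 10, 1) == 1.0  # mu = 1 >= r


def test_chernoff_monotone_decreasing_in_r():
    quals = [30] * 500 + [20] * 100
    ps = [chernoff_pvalue(quals, r) for r in range(0, 60)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_chernoff_dominates_monte_carlo_tail(rng):
    """The bound must upper-bound the true tail P[X >= r] for heterogeneous
    per-call error probabilities (Poisson-binomial), estimated by MC."""
    n_vectors, n_calls, reps = 1000, 120, 400
    failures = 0
    for _ in range(n_vectors):
        quals = rng.choice([37, 33, 30, 22, 12], size=n_calls,
                           p=[0.4, 0.2, 0.2, 0.15, 0.05])
        p = 10.0 ** (-0.1 * quals)
        mu = p.sum()
        r = int(np.ceil(mu * rng.uniform(1.5, 4.0)))
        sims = (rng.random((reps, n_calls)) < p).sum(axis=1)
        mc_tail = float(np.mean(sims >= r))
        bound = chernoff_pvalue(quals, r)
        se = math.sqrt(max(mc_tail * (1 - mc_tail), 1e-9) / reps)
        if bound < mc_tail - 3 * se:
            failures += 1
    assert failures == 0


# ---------------------------------------------------------------------------
# Flanking binomial test

def test_flanking_pure_reference_flanks():
    cols = make_region(n_sites=21, start=100, coverage=200,
                       variant_at=110, n_alt=60)
    site = cols[10]
    flanks = cols[:10] + cols[11:]
    p = flanking_pvalue(site, flanks)
    assert p < 1e-30  # site misses 30% of reference calls, flanks none


def test_flanking_exact_tail_sum_oracle():
    # p_flank = 0.99, n = 500, reference calls = 450
    site = make_column(pos=110, n_ref=450, n_alt=50)
    flanks = []
    for k in range(10):
        flanks.append(make_column(pos=99 - k, n_ref=99, n_alt=1))
        flanks.append(make_column(pos=121 + k, n_ref=99, n_alt=1))
    p = flanking_pvalue(site, flanks)
    oracle = sum(math.comb(500, k) * 0.99 ** k * 0.01 ** (500 - k)
                 for k in range(451))
    assert p == pytest.approx(oracle, rel=1e-9)


def test_flanking_no_signal_when_site_matches_flanks():
    # site and flanks share the same 2% error fraction
    site = make_column(pos=110, n_ref=196, n_alt=4)
    flanks = [make_column(pos=p, n_ref=196, n_alt=4)
              for p in list(range(100, 110)) + list(range(111, 121))]
    assert flanking_pvalue(site, flanks) > 0.3


def test_flanking_strand_specific():
    site = make_column(pos=110, n_ref=100, n_alt=40,
                       alt_forward=[True] * 40)  # all variants forward
    flanks = [make_column(pos=p, n_ref=100) for p in range(100, 110)]
    p_fwd = flanking_pvalue(site, flanks, strand="+")
    p_rev = flanking_pvalue(site, flanks, strand="-")
    assert p_fwd < 1e-10
    assert p_rev == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Prefilter and window

def test_prefilter_requires_two_per_strand():
    win = (20, 76)
    ok = make_column(n_alt=4, alt_forward=[True, True, False, False])
    assert prefilter_site(ok, win)["T"] is True
    one_sided = make_column(n_alt=4, alt_forward=[True] * 4)
    assert prefilter_site(one_sided, win)["T"] is False


def test_prefilter_quality_and_window():
    low_q = make_column(n_alt=4, alt_quality=25)
    assert prefilter_site(low_q, (20, 76))["T"] is False
    outside = make_column(n_alt=4, read_pos_alt=10)
    assert prefilter_site(outside, (20, 76))["T"] is False
    assert prefilter_site(outside, (5, 76))["T"] is True


def _profile_from_counts(mism, totals=None):
    from clonaltree.calling import ReadMismatchProfile

    mism = np.asarray(mism)
    totals = np.full_like(mism, 10000) if totals is None else totals
    return ReadMismatchProfile(mism, totals)


def test_window_uniform_profile_spans_full_read():
    prof = _profile_from_counts([40] * 76)
    assert determine_usable_window(prof) == (1, 76)


def test_window_trims_noisy_read_end():
    # uniform errors across 1..60, strong pile-up after position 60
    counts = [40] * 60 + [2000] * 16
    start, end = determine_usable_window(_profile_from_counts(counts))
    assert end == 60
    assert start == 1


def test_window_recovers_planted_uniform_region(rng):
    lam = np.full(76, 30.0)
    lam[:19] *= 8  # error pile-up at the start of the read
    counts = rng.poisson(lam)
    start, end = determine_usable_window(_profile_from_counts(counts))
    assert 17 <= start <= 22
    assert end == 76


def test_window_error_when_no_linear_segment(rng):
    counts = rng.integers(0, 2000, size=12) ** 2
    with pytest.raises(WindowDetectionError):
        determine_usable_window(_profile_from_counts(counts), r2_min=0.99999)


def test_mismatch_profile_counts():
    cols = [make_column(pos=100, n_ref=10),
            make_column(pos=101, n_ref=10, n_alt=3, read_pos_alt=33)]
    prof = compute_mismatch_profile(cols)
    assert prof.mismatches[32] == 3
    assert prof.mismatches.sum() == 3
    cum = prof.cumulative_fraction()
    assert cum[-1] == pytest.approx(1.0)


def test_mismatch_profile_all_reference_is_zero():
    prof = compute_mismatch_profile([make_column(n_ref=50)])
    assert prof.mismatches.sum() == 0


# ---------------------------------------------------------------------------
# call_variants / germline / gold set

def _region_with_variant(freq=0.30, coverage=300, n_sites=25):
    n_alt = round(freq * coverage)
    return make_region(n_sites=n_sites, start=100, coverage=coverage,
                       variant_at=112, n_alt=n_alt)


def test_call_variants_finds_planted_site():
    cols = _region_with_variant(freq=0.30)
    calls = call_variants(cols, (20, 76))
    assert len(calls) == 1
    m = calls[0]
    assert m.pos == 112 and m.alt_base == "T"
    assert m.frequency == pytest.approx(0.30, abs=0.01)
    assert all(p < 0.01 for p in m.adjusted_p)


def test_call_variants_frequency_floor():
    calls = call_variants(_region_with_variant(freq=0.02, coverage=500),
                          (20, 76))
    assert calls == []


def test_call_variants_coverage_floor():
    calls = call_variants(_region_with_variant(freq=0.30, coverage=40),
                          (20, 76))
    assert calls == []


def test_call_variants_empty_input():
    assert call_variants([], (20, 76)) == []


def test_call_variants_monotone_in_alpha():
    cols = _region_with_variant(freq=0.06, coverage=300)
    loose = call_variants(cols, (20, 76), CallerConfig(alpha=0.05))
    strict = call_variants(cols, (20, 76), CallerConfig(alpha=0.001))
    strict_pos = {m.pos for m in strict}
    assert strict_pos <= {m.pos for m in loose}


def test_subtract_germline():
    cols = _region_with_variant(freq=0.30)
    [call] = call_variants(cols, (20, 76))
    # hemizygous SNP in the normal: removed
    normal_het = [make_column(pos=112, n_ref=2, n_alt=198)]
    assert subtract_germline([call], normal_het) == []
    # clean normal: retained
    normal_clean = [make_column(pos=112, n_ref=200)]
    assert len(subtract_germline([call], normal_clean)) == 1
    # 10% contamination-like evidence: removed under default threshold
    normal_cont = [make_column(pos=112, n_ref=180, n_alt=20)]
    assert subtract_germline([call], normal_cont) == []
    # site absent from the normal: kept but flagged
    [kept] = subtract_germline([call], [])
    assert "no-normal-evidence" in kept.flags


def _som(freq, starts, n=500):
    r = round(freq * n)
    return SomaticMutation(chrom="c", pos=1, ref_base="A", alt_base="T",
                           r=r, n=n, frequency=r / n,
                           distinct_read_starts=starts)


@pytest.mark.parametrize("freq, starts, included", [
    (0.04, 7, True),
    (0.10, 5, False),
    (0.038, 20, False),
    (0.50, 30, True),
])
def test_gold_set_selection(freq, starts, included):
    got = select_gold_set([_som(freq, starts)])
    assert (len(got) == 1) is included
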