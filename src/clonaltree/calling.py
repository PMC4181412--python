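"""Error-model-based somatic variant calling for deep hemizygous pileups.

The caller targets very deep (hundreds-fold) targeted sequencing of a
single-copy chromosome, where subclonal point mutations down to a few
percent must be separated from sequencing and amplification error.  The
pipeline is:

1. a read-position usability window, learned from the cumulative
   distribution of high-quality mismatches along the read (library ends
   accumulate miscalls);
2. a strand-aware prefilter (>= 2 forward and >= 2 reverse Q>=30 variant
   calls inside the window);
3. two per-strand statistical tests: a Chernoff upper bound on the
   probability that the observed variant calls arise from per-base error
   (each call a Bernoulli with p_i = 10**(-Q_i/10)) and an exact binomial
   test of the site's reference-call deficit against the error level of
   the flanking sites;
4. Bonferroni correction over the candidate sites of the sample, a
   coverage floor and a frequency floor;
5. germline subtraction against the matched normal and gold-set selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .pileup_io import PileupColumn

HIGH_QUALITY = 30  # phred floor for "high quality" mismatch evidence

CATEGORIES = ("intergenic", "non-coding", "synonymous", "non-synonymous",
              "unannotated")


@dataclass
class CallerConfig:
    """Tunable thresholds of the variant-calling pipeline."""

    min_quality: int = HIGH_QUALITY
    alpha: float = 0.01            # threshold on each Bonferroni-adjusted P
    min_coverage: int = 50         # site kept only if n > min_coverage
    min_frequency: float = 0.027   # lowest reportable variant frequency
    window: tuple[int, int] | None = None  # explicit read-position window
    r2_min: float = 0.99           # linearity criterion for auto window
    gold_min_frequency: float = 0.04
    gold_min_read_starts: int = 7  # "more than six" distinct read starts
    germline_min_calls: int = 2
    germline_min_fraction: float = 0.05


@dataclass(frozen=True)
class ChernoffResult:
    """Chernoff tail bound for r observed variant calls.

    mu is the expected number of miscalls (sum of per-call error
    probabilities), delta = r/mu - 1 the relative excess, and p_bound the
    capped upper bound on P[X >= r].
    """

    mu: float
    delta: float
    p_bound: float


@dataclass
class SomaticMutation:
    """A called single-nucleotide somatic variant."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    r: int
    n: int
    frequency: float
    ci_low: float = 0.0
    ci_high: float = 1.0
    distinct_read_starts: int = 0
    # (chernoff fwd, chernoff rev, flanking fwd, flanking rev), adjusted
    adjusted_p: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    category: str = "unannotated"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("coverage must be positive")
        if not 0 < self.frequency <= 1:
            raise ValueError("frequency must lie in (0, 1]")


class ReadMismatchProfile:
    """Per-read-position counts of high-quality mismatches.

    ``mismatches[k]`` counts non-reference calls with Q >= 30 observed at
    1-based read position k+1 across all reads; ``totals[k]`` counts all
    calls at that read position.
    """

    def __init__(self, mismatches: np.ndarray, totals: np.ndarray) -> None:
        self.mismatches = np.asarray(mismatches, dtype=np.int64)
        self.totals = np.asarray(totals, dtype=np.int64)
        if (self.mismatches < 0).any() or (self.totals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.mismatches.shape != self.totals.shape:
            raise ValueError("mismatch/total length mismatch")

    @property
    def read_length(self) -> int:
        return len(self.mismatches)

    def cumulative_fraction(self) -> np.ndarray:
        """Cumulative share of all high-quality mismatches up to each
        read position (the curve whose linearity defines usable positions)."""
        cum = np.cumsum(self.mismatches, dtype=float)
        total = cum[-1] if len(cum) else 0.0
        return cum / total if total > 0 else cum


def compute_mismatch_profile(columns: Iterable[PileupColumn],
                             min_quality: int = HIGH_QUALITY,
                             ) -> ReadMismatchProfile:
    """Count Q>=min_quality mismatches per read position over a pileup."""
    max_len = 0
    mism: np.ndarray = np.zeros(0, dtype=np.int64)
    tot: np.ndarray = np.zeros(0, dtype=np.int64)
    for col in columns:
        if len(col) == 0:
            continue
        top = int(col.read_positions.max())
        if top > max_len:
            mism = np.pad(mism, (0, top - max_len))
            tot = np.pad(tot, (0, top - max_len))
            max_len = top
        keep = col.bases != "N"
        rp = col.read_positions[keep] - 1
        np.add.at(tot, rp, 1)
        bad = keep & (col.bases != col.ref_base) & (col.quals >= min_quality)
        np.add.at(mism, col.read_positions[bad] - 1, 1)
    return ReadMismatchProfile(mism, tot)


class WindowDetectionError(RuntimeError):
    """No usable read-position window satisfies the linearity criterion."""


def determine_usable_window(profile: ReadMismatchProfile,
                            r2_min: float = 0.99,
                            min_length: int = 10) -> tuple[int, int]:
    """Find the maximal read-position window with linear mismatch growth.

    Returns the 1-based inclusive window (start, end) maximising length
    among windows whose cumulative mismatch-count curve fits a straight
    line with R^2 >= r2_min.  Read positions outside the window (library
    ends that pile up miscalls) are excluded from variant evidence.
    """
    if profile.read_length == 0:
        raise WindowDetectionError("empty mismatch profile")
    y_all = np.cumsum(profile.mismatches, dtype=float)
    L = len(y_all)
    best: tuple[int, int] | None = None
    # O(L^2) scan with closed-form R^2; L is a read length (~100)
    for start in range(L):
        for end in range(start + min_length - 1, L):
            y = y_all[start:end + 1]
            x = np.arange(start, end + 1, dtype=float)
            vy = y.var()
            if vy == 0.0:  # flat segment: no mismatches -> trivially linear
                r2 = 1.0
            else:
                r = np.corrcoef(x, y)[0, 1]
                r2 = r * r
            if r2 >= r2_min:
                if best is None or (end - start) > (best[1] - best[0]):
                    best = (start, end)
    if best is None:
        raise WindowDetectionError(
            f"no window of length >= {min_length} fits a line with "
            f"R^2 >= {r2_min}; inspect the profile and set the window "
            "explicitly in the configuration")
    return best[0] + 1, best[1] + 1


def prefilter_site(column: PileupColumn, window: tuple[int, int],
                   min_quality: int = HIGH_QUALITY) -> dict[str, bool]:
    """Strand-aware mismatch prefilter.

    An alternate base passes iff it is supported by at least two forward
    and two reverse calls with Q >= min_quality whose read position lies
    inside the (1-based, inclusive) usable window.  Recurring amplification
    artefacts and low-quality miscalls fail this filter.
    """
    lo, hi = window
    in_win = (column.read_positions >= lo) & (column.read_positions <= hi)
    good = in_win & (column.quals >= min_quality)
    out: dict[str, bool] = {}
    for alt in column.alternate_bases():
        support = good & (column.bases == alt)
        fwd = int(np.sum(support & column.forward))
        rev = int(np.sum(support & ~column.forward))
        out[alt] = fwd >= 2 and rev >= 2
    return out


def chernoff_bound(qualities: Sequence[int] | np.ndarray,
                   r: int) -> ChernoffResult:
    """Chernoff upper bound on observing >= r miscalls among the calls.

    Each call i is a Bernoulli error with p_i = 10**(-Q_i/10); with
    mu = sum_i p_i and delta = r/mu - 1 the bound is
    ``[e**delta / (1+delta)**(1+delta)]**mu``, evaluated in log space and
    capped at 1.  The bound only holds for delta > 0, so r <= mu returns
    1.  mu = 0 with r > 0 is impossible under the error model and returns
    a bound of 0.
    """
    q = np.asarray(qualities, dtype=float)
    n = len(q)
    if n < 1:
        raise ValueError("at least one base call required")
    if not 0 <= r <= n:
        raise ValueError(f"r={r} outside [0, {n}]")
    mu = float(np.sum(10.0 ** (-0.1 * q)))
    if mu == 0.0:
        return ChernoffResult(0.0, math.inf if r else 0.0,
                              0.0 if r > 0 else 1.0)
    if r <= mu:
        return ChernoffResult(mu, r / mu - 1.0, 1.0)
    delta = r / mu - 1.0
    log_p = mu * (delta - (1.0 + delta) * math.log1p(delta))
    return ChernoffResult(mu, delta, math.exp(min(0.0, log_p)))


def chernoff_pvalue(qualities: Sequence[int] | np.ndarray, r: int) -> float:
    return chernoff_bound(qualities, r).p_bound


class FlankingCoverageError(RuntimeError):
    """Flanking sites carry no coverage; the test is undefined."""


def flanking_pvalue(column: PileupColumn,
                    flank_columns: Sequence[PileupColumn],
                    strand: str | None = None) -> float:
    """Exact binomial test of the site's reference deficit against flanks.

    The reference-call fraction is averaged over the five and the ten
    nearest sequenced sites on each side (the two window means are
    themselves averaged) to give the local per-call probability p_flank of
    reading the reference.  The returned P is the lower tail
    ``P[Binom(n, p_flank) <= observed reference calls]``: a small value
    means the site is missing reference calls far beyond what regional
    error explains, i.e. supports a real variant.  Edge sites use whatever
    flanking sites are available; zero available flank coverage raises
    :class:`FlankingCoverageError`.
    """
    def ref_fraction(cols: Sequence[PileupColumn]) -> tuple[int, int]:
        ref = tot = 0
        for c in cols:
            keep = c.bases != "N"
            if strand == "+":
                keep &= c.forward
            elif strand == "-":
                keep &= ~c.forward
            tot += int(np.sum(keep))
            ref += int(np.sum(keep & (c.bases == c.ref_base)))
        return ref, tot

    by_dist = sorted(flank_columns, key=lambda c: abs(c.pos - column.pos))
    left = [c for c in by_dist if c.pos < column.pos]
    right = [c for c in by_dist if c.pos > column.pos]
    p_parts = []
    for k in (5, 10):
        ref, tot = ref_fraction(left[:k] + right[:k])
        if tot > 0:
            p_parts.append(ref / tot)
    if not p_parts:
        raise FlankingCoverageError(
            f"no flank coverage around {column.chrom}:{column.pos}")
    p_flank = float(np.mean(p_parts))

    keep = column.bases != "N"
    if strand == "+":
        keep &= column.forward
    elif strand == "-":
        keep &= ~column.forward
    n = int(np.sum(keep))
    if n == 0:
        raise FlankingCoverageError(
            f"no {strand or 'any'}-strand coverage at "
            f"{column.chrom}:{column.pos}")
    ref_calls = int(np.sum(keep & (column.bases == column.ref_base)))
    return float(stats.binom.cdf(ref_calls, n, p_flank))


def _strand_chernoff(column: PileupColumn, alt: str, forward: bool) -> float:
    sel = column.forward if forward else ~column.forward
    sel = sel & (column.bases != "N")
    quals = column.quals[sel]
    if len(quals) == 0:
        return 1.0
    r = int(np.sum(sel & (column.bases == alt)))
    return chernoff_pvalue(quals, r)


def call_variants(tumor: Sequence[PileupColumn],
                  window: tuple[int, int],
                  config: CallerConfig | None = None,
                  ) -> list[SomaticMutation]:
    """Run the per-site tests over a tumor pileup and return candidates.

    Every surviving site carries four Bonferroni-adjusted P values
    (Chernoff and flanking, each computed separately on forward-only and
    reverse-only calls); the Bonferroni family is the number of candidate
    variant sites in the sample (those passing the prefilter).  A site is
    retained iff all four adjusted P fall below ``alpha``, coverage
    exceeds ``min_coverage`` and the variant frequency r/n is at least
    ``min_frequency``.
    """
    cfg = config or CallerConfig()
    tumor = list(tumor)
    # candidate discovery (defines the Bonferroni family)
    candidates: list[tuple[int, str]] = []
    for idx, col in enumerate(tumor):
        if len(col) == 0:
            continue
        passed = prefilter_site(col, window, cfg.min_quality)
        for alt, ok in passed.items():
            if ok:
                candidates.append((idx, alt))
    n_family = len(candidates)
    out: list[SomaticMutation] = []
    for idx, alt in candidates:
        col = tumor[idx]
        n = col.coverage
        r = col.variant_count(alt)
        if n <= cfg.min_coverage:
            continue
        freq = r / n
        if freq < cfg.min_frequency:
            continue
        flanks = [c for c in tumor[max(0, idx - 10):idx + 11]
                  if c.pos != col.pos and c.chrom == col.chrom]
        try:
            p_ff = flanking_pvalue(col, flanks, strand="+")
            p_fr = flanking_pvalue(col, flanks, strand="-")
        except FlankingCoverageError:
            continue  # site rejected: no flank evidence available
        p_cf = _strand_chernoff(col, alt, forward=True)
        p_cr = _strand_chernoff(col, alt, forward=False)
        adj = tuple(min(1.0, p * n_family) for p in (p_cf, p_cr, p_ff, p_fr))
        if any(p >= cfg.alpha for p in adj):
            continue
        starts = col.read_starts[(col.bases == alt)]
        out.append(SomaticMutation(
            chrom=col.chrom, pos=col.pos, ref_base=col.ref_base,
            alt_base=alt, r=r, n=n, frequency=freq,
            distinct_read_starts=len(np.unique(starts)),
            adjusted_p=adj,
        ))
    return out


def subtract_germline(candidates: Iterable[SomaticMutation],
                      normal: Sequence[PileupColumn],
                      config: CallerConfig | None = None,
                      ) -> list[SomaticMutation]:
    """Remove candidates whose alternate allele shows in the normal.

    A candidate is discarded iff the matched normal carries the alternate
    allele with at least ``germline_min_calls`` calls *and* at least
    ``germline_min_fraction`` of the normal coverage (hemizygous germline
    variants sit near 100%, contamination well above the per-base error
    floor).  Candidates at sites absent from the normal pileup are kept
    but flagged ``no-normal-evidence``.
    """
    cfg = config or CallerConfig()
    lookup = {(c.chrom, c.pos): c for c in normal}
    survivors: list[SomaticMutation] = []
    for mut in candidates:
        col = lookup.get((mut.chrom, mut.pos))
        if col is None or col.coverage == 0:
            survivors.append(replace(
                mut, flags=mut.flags + ("no-normal-evidence",)))
            continue
        alt_calls = col.variant_count(mut.alt_base)
        if (alt_calls >= cfg.germline_min_calls
                and alt_calls / col.coverage >= cfg.germline_min_fraction):
            continue
        survivors.append(mut)
    return survivors


def select_gold_set(profile: Iterable[SomaticMutation],
                    config: CallerConfig | None = None,
                    ) -> list[SomaticMutation]:
    """High-confidence subset: frequency >= 4% and > 6 distinct read starts.

    The frequency floor matches the validation limit of orthogonal assays;
    the read-start requirement guards against PCR amplification distorting
    the frequency of a genuinely present variant.
    """
    cfg = config or CallerConfig()
    return [m for m in profile
            if m.frequency >= cfg.gold_min_frequency
            and m.distinct_read_starts >= cfg.gold_min_read_starts]
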