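"""Confidence-interval clustering of somatic mutation frequencies.

On a hemizygous chromosome the variant allele frequency of a somatic
mutation equals the fraction of tumor cells carrying it, so mutations
acquired at the same stage of the clonal expansion share a frequency up
to binomial sampling noise.  Clustering proceeds directly on the exact
95% binomial (Clopper-Pearson) confidence intervals:

1. *seeds* -- mutations whose CI overlaps no other mutation's CI, or, in
   case of overlap, the mutations with the smallest CIs that are mutually
   non-overlapping; seeds have the most precise frequency estimates and
   fix the number of clusters;
2. *unambiguous assignment* -- every mutation whose CI overlaps exactly
   one seed CI joins that seed; provisional cluster frequencies are the
   pooled ratios sum(r_i)/sum(n_i) over these members;
3. *ambiguous assignment* -- each remaining mutation joins the cluster
   under whose provisional frequency its (r, n) has the highest exact
   binomial test probability.

Touching intervals count as overlapping.  Seeds are never re-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calling import SomaticMutation

CI_LEVEL = 0.95


def frequency_ci(r: int, n: int, level: float = CI_LEVEL,
                 ) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI for a binomial proportion.

    The bounds invert the binomial tails through the beta quantile
    function; the interval is conservative (coverage >= level for every
    true proportion).  r = 0 pins the lower bound at 0 and r = n the
    upper bound at 1.
    """
    if n < 1:
        raise ValueError("coverage n must be >= 1")
    if not 0 <= r <= n:
        raise ValueError(f"r={r} outside [0, {n}]")
    alpha = 1.0 - level
    lo = 0.0 if r == 0 else float(stats.beta.ppf(alpha / 2, r, n - r + 1))
    hi = 1.0 if r == n else float(stats.beta.ppf(1 - alpha / 2, r + 1, n - r))
    return lo, hi


def _overlap(a: SomaticMutation, b: SomaticMutation) -> bool:
    # shared endpoints count as overlap
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high


def with_confidence_intervals(mutations: Iterable[SomaticMutation],
                              level: float = CI_LEVEL) -> list[SomaticMutation]:
    """Return mutations with ci_low/ci_high populated at ``level``.

    Vectorised Clopper-Pearson over the whole profile (the stability
    simulations recompute intervals thousands of times).
    """
    out = list(mutations)
    if not out:
        return out
    r = np.array([m.r for m in out], dtype=float)
    n = np.array([m.n for m in out], dtype=float)
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        lo = np.where(r == 0, 0.0, stats.beta.ppf(alpha / 2, r, n - r + 1))
        hi = np.where(r == n, 1.0,
                      stats.beta.ppf(1 - alpha / 2, r + 1, n - r))
    for m, a, b in zip(out, lo, hi):
        m.ci_low, m.ci_high = float(a), float(b)
    return out


def find_seeds(mutations: Sequence[SomaticMutation],
               ) -> list[SomaticMutation]:
    """Select cluster seeds by iterated smallest-CI acceptance.

    Mutations are visited in order of ascending CI width (ties: lower
    frequency, then genomic position, for deterministic output); one is
    accepted as a seed iff its CI overlaps no already-accepted seed's CI.
    Mutations overlapping nothing at all are therefore always accepted.
    The accepted seeds are pairwise non-overlapping and fix the number
    of clusters.
    """
    order = sorted(mutations,
                   key=lambda m: (m.ci_high - m.ci_low, m.frequency,
                                  m.chrom, m.pos))
    seeds: list[SomaticMutation] = []
    for m in order:
        if not any(_overlap(m, s) for s in seeds):
            seeds.append(m)
    return seeds


@dataclass
class MutationCluster:
    """A frequency cluster of somatic mutations."""

    seed: SomaticMutation
    members: list[SomaticMutation] = field(default_factory=list)
    f: float = 0.0          # pooled frequency sum(r)/sum(n) over members
    is_clonal: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    def pooled_frequency(self, members=None) -> float:
        ms = self.members if members is None else members
        tot_n = sum(m.n for m in ms)
        return sum(m.r for m in ms) / tot_n if tot_n else 0.0


def _binom_two_sided(r: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Exact two-sided binomial P (doubled smaller tail, capped at 1)."""
    lower = stats.binom.cdf(r, n, p)
    upper = stats.binom.sf(r - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def cluster_mutations(mutations: Sequence[SomaticMutation],
                      seeds: Sequence[SomaticMutation],
                      ) -> list[MutationCluster]:
    """Two-step assignment of mutations to seeds (see module docstring).

    Returns clusters sorted by descending pooled frequency; the first is
    flagged clonal.  The clusters partition the input.
    """
    if not seeds:
        return []
    clusters = [MutationCluster(seed=s) for s in seeds]
    ambiguous: list[SomaticMutation] = []
    for m in mutations:
        hits = [c for c in clusters if _overlap(m, c.seed)]
        if len(hits) == 1:
            hits[0].members.append(m)
        else:
            ambiguous.append(m)
    # provisional frequencies from unambiguous members only
    provisional = [c.pooled_frequency() for c in clusters]
    if ambiguous:
        r = np.array([m.r for m in ambiguous], dtype=float)
        n = np.array([m.n for m in ambiguous], dtype=float)
        pvals = np.column_stack([
            _binom_two_sided(r, n, p) for p in provisional])
        freqs = np.array([m.frequency for m in ambiguous])
        dist = np.abs(freqs[:, None] - np.array(provisional)[None, :])
        # argmax P; ties broken toward the nearest provisional frequency
        for i, m in enumerate(ambiguous):
            best = np.flatnonzero(pvals[i] == pvals[i].max())
            j = best[np.argmin(dist[i, best])]
            clusters[int(j)].members.append(m)
    for c in clusters:
        c.f = c.pooled_frequency()
    clusters.sort(key=lambda c: -c.f)
    for c in clusters:
        c.is_clonal = False
    if clusters:
        clusters[0].is_clonal = True
    return clusters


def cluster_profile(mutations: Sequence[SomaticMutation],
                    level: float = CI_LEVEL) -> list[MutationCluster]:
    """CI assignment + seed selection + two-step clustering in one call."""
    ms = with_confidence_intervals(mutations, level)
    return cluster_mutations(ms, find_seeds(ms))


def expected_cluster_size(cluster: MutationCluster,
                          coverage_values: Sequence[int] | np.ndarray,
                          ) -> float:
    """Detection-corrected expected mutation count for a cluster.

    A mutation of this cluster is only callable at positions covered at
    least as deep as its own site, so the expected count is the observed
    count divided by the fraction of all sequenced positions whose
    coverage reaches the minimum coverage among the cluster's members.
    """
    cov = np.asarray(coverage_values)
    if len(cov) == 0:
        raise ValueError("coverage distribution is empty")
    min_cov = min(m.n for m in cluster.members)
    fraction = float(np.mean(cov >= min_cov))
    if fraction == 0.0:
        raise ValueError(
            f"no sequenced position reaches coverage {min_cov}; expected "
            "size undefined")
    return cluster.size / fraction
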