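"""Synthetic stand-ins for the four-adenoma study tables.

Everything in this module is SYNTHETIC.  The original study's per-mutation
supplementary tables are not redistributable, so the published summary
values are encoded here and per-mutation detail is regenerated around
them with frozen seeds:

* per-sample somatic mutation totals 367 / 56 / 168 / 180 (sum 771, of
  which 638 intergenic and 49 non-synonymous);
* cluster ladders with frequency ratios giving n_ext = 15, 9, 20 and 14
  for A1, A2, A3 and A4;
* internal cluster values {12,9,7,5,3,2} (A1), {6,3,2} (A2),
  {18,16,14,12,6,4,3,2} (A3) and {12,9,7,5,3,2} (A4), reconstructed so
  that A1/A2/A4 admit exactly one compatible proliferation tree, A3
  admits four almost identical ones, and the joint chance probability of
  the four compatibility successes is 1.1e-4;
* a ten-point allele-dilution ladder spanning 4%-41% for the qPCR vs
  deep-sequencing frequency-accuracy check.

The tables are deterministic: a fixed construction seed freezes the
per-mutation draws, so they behave as a dataset, not a simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import SomaticMutation
from .trees import NodeCombination

#: frozen construction seed (dataset identity, not a tunable)
_TABLE_SEED = 20140830

SAMPLES = ("A1", "A2", "A3", "A4")

#: Cluster value ladders (leaf counts, descending; 1 = leaf cluster).
CLUSTER_VALUES: dict[str, tuple[int, ...]] = {
    "A1": (15, 12, 9, 7, 5, 3, 2, 1),
    "A2": (9, 6, 3, 2, 1),
    "A3": (20, 18, 16, 14, 12, 6, 4, 3, 2, 1),
    "A4": (14, 12, 9, 7, 5, 3, 2, 1),
}

#: Cluster sizes (mutations per cluster, aligned with CLUSTER_VALUES).
CLUSTER_SIZES: dict[str, tuple[int, ...]] = {
    "A1": (170, 75, 55, 18, 14, 12, 11, 12),     # sums to 367
    "A2": (30, 10, 6, 5, 5),                     # sums to 56
    "A3": (30, 24, 22, 20, 18, 14, 12, 10, 9, 9),  # sums to 168
    "A4": (78, 38, 25, 12, 8, 7, 6, 6),          # sums to 180
}

#: Clonal-cluster mean frequency (the tumor-cell fraction of the sample).
CLONAL_FREQUENCY: dict[str, float] = {
    "A1": 0.57, "A2": 0.54, "A3": 0.60, "A4": 0.56,
}

#: Typical sequencing depth of the profile's called sites.
PROFILE_DEPTH: dict[str, float] = {
    "A1": 900.0, "A2": 900.0, "A3": 1500.0, "A4": 900.0,
}

#: Somatic mutation totals per sample (sum = 771).
MUTATION_TOTALS: dict[str, int] = {"A1": 367, "A2": 56, "A3": 168, "A4": 180}

#: Annotation category totals across the cohort.
CATEGORY_TOTALS = {"intergenic": 638, "non-synonymous": 49,
                   "synonymous": 40, "non-coding": 44}


def sample_node_combination(sample: str) -> NodeCombination:
    """The node combination encoded by a sample's cluster ladder."""
    vals = CLUSTER_VALUES[sample]
    return NodeCombination(
        n_ext=vals[0],
        internal_values=tuple(v for v in vals if 1 < v < vals[0]))


def combination_space_parameters() -> list[tuple[int, int]]:
    """(n_ext, number of internal clusters) for the four samples."""
    out = []
    for sample in SAMPLES:
        combo = sample_node_combination(sample)
        out.append((combo.n_ext, len(combo.internal_values)))
    return out


def cohort_cluster_table() -> pd.DataFrame:
    """Cluster ladders of the four samples (one row per cluster)."""
    rows = []
    for sample in SAMPLES:
        vals = CLUSTER_VALUES[sample]
        f_min = CLONAL_FREQUENCY[sample] / vals[0]
        for value, size in zip(vals, CLUSTER_SIZES[sample]):
            rows.append({"sample": sample, "value": value,
                         "mean_frequency": value * f_min, "size": size})
    return pd.DataFrame(rows)


def mutation_catalog() -> pd.DataFrame:
    """Per-mutation annotation categories for the cohort (synthetic).

    Categories are spread across samples proportionally to their mutation
    totals while matching the cohort-level category totals exactly.
    """
    totals = np.array([MUTATION_TOTALS[s] for s in SAMPLES], dtype=int)
    grand = totals.sum()
    rows = []
    remaining = {cat: count for cat, count in CATEGORY_TOTALS.items()}
    for i, sample in enumerate(SAMPLES):
        quota = totals[i]
        cats = []
        for j, (cat, cohort_count) in enumerate(CATEGORY_TOTALS.items()):
            if i < len(SAMPLES) - 1:
                take = int(round(cohort_count * totals[i] / grand))
                take = min(take, remaining[cat])
            else:
                take = remaining[cat]
            cats += [cat] * take
            remaining[cat] -= take
        # proportional rounding can leave the sample total slightly off;
        # pad/trim on the dominant category
        while len(cats) < quota:
            cats.append("intergenic")
            remaining["intergenic"] -= 1
        while len(cats) > quota:
            removed = cats.pop(cats.index("intergenic"))
            remaining[removed] += 1
        rows += [{"sample": sample, "category": c} for c in cats]
    df = pd.DataFrame(rows)
    assert len(df) == grand
    return df


def _draw_cluster_members(rng: np.random.Generator, sample: str,
                          value: int, size: int,
                          mean_coverage: float | None = None,
                          coverage_shape: float = 40.0,
                          min_frequency: float = 0.027,
                          ) -> list[SomaticMutation]:
    vals = CLUSTER_VALUES[sample]
    f = value * CLONAL_FREQUENCY[sample] / vals[0]
    if mean_coverage is None:
        mean_coverage = PROFILE_DEPTH[sample]
    mu = mean_coverage - 300
    p = coverage_shape / (coverage_shape + mu)
    from .clustering import frequency_ci

    # members: (coverage, variant count) drawn jointly conditional on
    # being callable (frequency floor, strand prefilter) and on the
    # member's own CI covering the cluster frequency -- the table's
    # cluster membership is a given, not an inference, so members
    # inconsistent with their cluster are invalid draws
    pairs: list[tuple[int, int]] = []
    while len(pairs) < size:
        n = 300 + int(rng.negative_binomial(coverage_shape, p))
        r = int(rng.binomial(n, f))
        if r < 4 or r / n < min_frequency:
            continue
        lo, hi = frequency_ci(r, n)
        if lo <= f <= hi:
            pairs.append((n, r))
    # pin the pooled cluster frequency to the ladder value by +/-1 tweaks
    # spread over the routine members (each member's frequency moves by
    # O(1/n); the ladder is the dataset's defining summary statistic)
    total_n = sum(n for n, _ in pairs)
    delta = int(round(f * total_n)) - sum(r for _, r in pairs)
    step = 1 if delta > 0 else -1
    guard = 0
    while delta != 0 and size > 1 and guard < 10 * abs(delta) + 100:
        i = 1 + guard % (size - 1)
        n, r = pairs[i]
        r_new = r + step
        if max(4, int(np.ceil(min_frequency * n))) <= r_new <= n:
            pairs[i] = (n, r_new)
            delta -= step
        guard += 1
    out = []
    for n, r in pairs:
        starts = int(rng.integers(7, 40)) if rng.random() > 0.03 else \
            int(rng.integers(2, 7))
        out.append(SomaticMutation(
            chrom="chrX", pos=0, ref_base="C", alt_base="T",
            r=r, n=n, frequency=r / n, distinct_read_starts=starts,
            adjusted_p=(1e-4, 1e-4, 1e-4, 1e-4), category="intergenic"))
    return out


def adenoma_profile(sample: str = "A1",
                    seed: int = _TABLE_SEED) -> list[SomaticMutation]:
    """Frozen synthetic mutation profile of one adenoma.

    Mutations are drawn cluster by cluster: binomial variant counts at
    overdispersed capture coverage around each cluster's mean frequency,
    truncated at the 2.7% reporting floor, with annotation categories
    from :func:`mutation_catalog`.
    """
    if sample not in SAMPLES:
        raise ValueError(f"unknown sample {sample!r}")
    rng = np.random.default_rng([seed, SAMPLES.index(sample)])
    muts: list[SomaticMutation] = []
    for value, size in zip(CLUSTER_VALUES[sample], CLUSTER_SIZES[sample]):
        muts += _draw_cluster_members(rng, sample, value, size)
    positions = np.sort(rng.choice(150_000_000, size=len(muts),
                                   replace=False))
    cats = mutation_catalog()
    cats = cats[cats["sample"] == sample]["category"].tolist()
    for m, pos, cat in zip(muts, positions, cats):
        m.pos = int(pos) + 1
        m.category = cat
    return muts


def dilution_series(seed: int = _TABLE_SEED) -> pd.DataFrame:
    """Synthetic ten-point allele-dilution ladder (4%-41%).

    Two homozygous genotypes mixed in known molar ratios; the mixed
    fraction is measured once by qPCR (small multiplicative quantification
    error) and once by deep sequencing (binomial read sampling at
    amplicon-level coverage).  Columns: nominal, qpcr, coverage, reads,
    illumina.
    """
    nominal = np.array([0.04, 0.06, 0.09, 0.12, 0.16,
                        0.20, 0.25, 0.30, 0.35, 0.41])
    rng = np.random.default_rng([seed, 99])
    qpcr = np.clip(nominal + rng.normal(0.0, 0.005, size=len(nominal)),
                   0.005, 0.995)
    coverage = rng.integers(2200, 4200, size=len(nominal))
    reads = rng.binomial(coverage, nominal)
    return pd.DataFrame({
        "nominal": nominal, "qpcr": qpcr, "coverage": coverage,
        "reads": reads, "illumina": reads / coverage,
    })
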