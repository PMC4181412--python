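# Methods

## Model

A monoclonal expansion is represented as a rooted full binary tree:
every internal node is a cell division, every leaf a lineage that
survived to the final population.  Two assumptions carry all the
inference: (1) daughters inherit every mutation of the parent and pass
old and new mutations on (direct parent–descent relationship between
all tumor cells), and (2) only mutations carried by lineages that
escaped extinction are visible, so the reconstructed tree is the
*minimum-evolution* record of the surviving population, not the full
division history.  A division in which one daughter line dies leaves
no branching in that record.

On a copy-neutral hemizygous region, a mutation present in a fraction
*q* of tumor cells is read at allele frequency *q* (times sample
purity).  Mutations arising in the cell at a node with *k* surviving
leaf descendants have frequency *k*/N_ext relative to the clonal
(root) frequency, so the cluster ladder of observed frequencies,
divided by its lowest rung, is a multiset of integers
N_tot = {N_ext, (N_int)ᵢ, …, 1}: the leaf counts that some tree must
realise.

Compatibility is deliberately strict: every node's leaf count must be
one of the admissible values ({N_ext} ∪ internal values ∪ {1});
values are reusable across nodes, and each internal value must be
realised at least as often as its multiplicity in N_tot.  Strictness
is what makes compatibility rare — most subsets of [2, N_ext−1] admit
no tree at all — and therefore informative.  The empty internal set is
the one exception: with no internal cluster there is nothing to
constrain, and any full binary tree realises {N_ext, 1}.

### Chance probability

For a sample with N_ext external nodes and c internal clusters, all
C(N_ext−2, c) subsets of distinct values from [2, N_ext−1] are
enumerated and tested for compatibility (a bitmask coverage dynamic
program over achievable value sets, pruned to maximal masks, decides
existence without materialising trees).  The probability that *every*
sample of a cohort would admit a compatible tree had its internal
values been arbitrary is the product of the per-sample success
fractions.  For the bundled cohort parameters, (183/1716) × (3/35) ×
(3199/43758) × (155/924) ≈ 1.1 × 10⁻⁴.  A pooled ratio
(Σ successes / Σ totals) is *not* used: its minimum over all cluster
counts is ~2.9 × 10⁻³, far above the joint probability, because the
sample with the largest subset space dominates the pool.

### Candidate-tree counts

The number of possible histories for N_ext external nodes is counted
by the standard convolution recurrence for unlabeled rooted trees on
n nodes (exact integer arithmetic, cached): 1, 1, 2, 4, 9, 20, 48,
115, 286, …, giving 286 / 32,973 / 87,811 / 12,826,228 for n = 9, 14,
15, 20.

## Variant calling

Per-call error probability is taken at face value from the phred
quality, pᵢ = 10^(−Qᵢ/10).  With μ = Σpᵢ the expected miscall count
at a site and r observed variant calls, the Chernoff bound

  P[X > (1+δ)μ] < [e^δ / (1+δ)^(1+δ)]^μ,  δ = r/μ − 1

is evaluated in log space and capped at 1; r ≤ μ returns 1 (the bound
holds only for δ > 0) and μ = 0 with r > 0 returns 0.  The flanking
test estimates the local reference-call fraction by averaging the
5-site and 10-site flanking means and computes the exact lower
binomial tail of the observed reference count: small P means the
site's reference deficit exceeds regional noise, supporting a real
variant.  (The lower tail is deliberate; an upper-tail reading would
make true variants non-significant and is incompatible with the
retention rule "keep sites with all adjusted P below α".)  Both tests
run separately on forward-only and reverse-only calls; the four P
values are Bonferroni-multiplied by the number of candidate sites
surviving the prefilter.  Defaults: Q ≥ 30 for mismatch evidence, ≥2
forward and ≥2 reverse supporting calls inside the usable window,
α = 0.01, coverage > 50×, frequency ≥ 2.7% (frequency floors are
applied before germline subtraction).  The usable read-position window
is the longest window (≥10 positions) whose cumulative high-quality
mismatch curve fits a line with R² ≥ 0.99, overridable by explicit
configuration.  Germline removal uses the matched normal only: the
alternate allele with ≥2 calls and ≥5% of normal coverage is
considered germline evidence; candidates without normal coverage are
kept but flagged.  Both germline thresholds are package choices.  The
gold set (frequency ≥ 4%, > 6 distinct read starts) guards the tree
against PCR-amplification frequency distortion.

## Clustering

Confidence intervals are exact Clopper–Pearson (conservative and
exactly invertible; empirical coverage ≥ 95% by construction).
Touching intervals count as overlapping.  Seeds are accepted greedily
in order of ascending CI width (ties: lower frequency, then position)
iff they overlap no previously accepted seed; seeds are never
re-assigned afterwards.  Step 1 assigns every mutation overlapping
exactly one seed; provisional cluster frequencies are pooled ratios
Σrᵢ/Σnᵢ over those members (the pooled ratio weights deep sites more,
as it should).  Step 2 assigns each remaining mutation to the cluster
maximising the exact two-sided binomial test probability of (rᵢ, nᵢ)
under the provisional frequency — two-sided via the doubled smaller
tail, capped at 1, which vectorises over the profile; ties go to the
cluster with the nearer mean.  Final frequencies are recomputed over
the full membership.  Ratios are rounded half-up to integers.

A known limitation of the greedy seed rule: a large cluster can emit
an extreme member whose interval clears the accepted seed while still
overlapping looser non-seed members; such an outlier becomes an extra
seed and splits the cluster.  At the coverage of the bundled cohort
this channel is inactive for unperturbed data (every member's CI
covers its cluster frequency) but contributes to the spread of the
perturbation-study histograms, which is consistent with the intended
behaviour of that simulation.

Expected cluster sizes divide the observed count by the fraction of
all sequenced positions whose coverage reaches the cluster's minimum
member coverage — a detection correction that explains why
low-frequency clusters run below expectation.

## Stability simulations

The perturbation study redraws the frequency of ⌊fraction·N⌋ randomly
chosen mutations uniformly within each mutation's own 95% CI
(realised as a new variant count at fixed coverage, so the interval
machinery stays consistent; the uniform redraw is a package choice —
only the support is specified by the procedure), re-clusters, and
histograms the cluster count.  The deletion study drops
⌊fraction·N⌋ mutations, re-clusters and histograms the canonical node
combination.  One master seed spawns an independent substream per
iteration, so reports are bitwise reproducible and order-independent.
Seeds are not protected from perturbation.

## Synthetic data

### Clonal-expansion simulator

Planted mode realises a requested node combination exactly (first
canonical compatible tree); stochastic mode runs a synchronous
branching process with per-daughter death probability and collapses
non-branching divisions.  Per-node mutation counts are Poisson
(default rate 8); true frequencies are leaf-count fractions.  The
renderer draws per-site coverage from a negative binomial (default
mean 300×, dispersion 8 — capture unevenness), qualities from a
discrete distribution concentrated at Q33–Q37, read positions
uniformly over a 76 bp read with a ×3 error multiplier outside the
[20, 76] usable window, PCR-duplicate read starts at rate 0.1, and
purity-scaled allele draws (purity default 1.0; truth tables report
cell fractions scaled by purity).  An optional transition-biased
substitution signature is not modelled: downstream mathematics is
signature-agnostic.

What the simulator does not emulate: alignment artefacts, indels,
copy-number change, strand bias, overlapping read pairs, and
context-dependent error — so passing end-to-end tests demonstrates
correctness of the statistical machinery under the stated error
model, not robustness to every artefact of real libraries.

### Cohort stand-ins

`synthetic_cohort` regenerates, from frozen seeds, per-mutation tables
for a four-adenoma cohort whose *summary* statistics are fixed inputs:
sample totals 367/56/168/180 (638 of 771 intergenic), clonal
frequencies 0.54–0.60, cluster ladders with N_ext = 15/9/20/14, one
compatible tree for A1/A2/A4 and four almost-identical trees for A3,
and a ten-point 4–41% dilution ladder.  Members are drawn jointly
(coverage, variant count) conditional on callability and on the
member's CI covering its own cluster frequency — membership is a datum
of the table, not an inference — at homogeneous per-sample depth
(900×, 900×, 1500×, 900× at called sites; called sites skew deeper
than the genome-wide mean because detection at low frequency requires
depth), and each cluster's pooled frequency is pinned to its ladder
value by ±1-read adjustments spread across members.  Depths were fixed
at the lowest values for which the frozen tables reproduce the
qualitative behaviour the cohort is defined by: exact structure
recovery, perturbation-histogram median equal to the observed cluster
count, and majority concentration at 40% perturbation in all four
samples.  These tables are labelled synthetic throughout; they are
calibration datasets, not simulations.

## Numerical choices

* Chernoff bound in log space; exp only after capping at 0.
* Clopper–Pearson through `scipy.stats.beta.ppf`, vectorised across a
  profile; r = 0 and r = n pin the respective bound.
* Tree enumeration memoises canonical subtree lists per value;
  canonical form sorts siblings by nested-tuple order, so unordered
  trees deduplicate exactly.
* Ratio rounding is floor(x + 0.5) (half-up, no banker's rounding).
* The existence DP's per-value mask sets are pruned to maximal
  elements; correctness is cross-checked against brute-force
  enumeration for all N_ext ≤ 8 in the test suite.
* Problem sizes in tests and simulations (2 kb genomes at 300×, 20
  replicates, 1,000-iteration stability runs) were chosen so the whole
  suite runs in well under a minute per heavy test while keeping every
  statistical check at its stated power.

## Known limitations

* No purity/contamination correction: frequencies are taken as cell
  fractions, which is exactly right only for copy-neutral hemizygous
  regions.
* Single best alternate allele per site; indels out of scope.
* The greedy seed rule's split channel (above) makes cluster *counts*
  less stable than cluster *means* under perturbation.
* Tree enumeration is exponential in principle; it is fast for
  realistic N_tot (sparse admissible sets) but not for dense value
  sets at large N_ext.
* The stochastic growth mode stops when the surviving population first
  reaches the target, a simplification of continuous growth.
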