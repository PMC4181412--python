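# clonaltree

Reconstruction of the proliferation history of a monoclonal tumor from
deep sequencing of a hemizygous chromosome.

A monoclonal tumor grows from one founder cell; each division hands all
existing somatic mutations to both daughters and adds new ones.  On a
copy-neutral hemizygous region (the X chromosome of a male patient) the
variant allele frequency of every somatic mutation equals the fraction
of tumor cells that carry it, with no heterozygous dosage ambiguity.
The frequency spectrum of the mutation profile therefore encodes the
shape of the expansion, and `clonaltree` decodes it in three steps:

1. **Variant calling** (`clonaltree.calling`) — somatic point mutations
   down to ~3% frequency are separated from sequencing error with a
   read-position usability window, strand-aware prefilters, a Chernoff
   upper bound on the probability that *r* variant calls in *n* arise
   from per-base error (each call a Bernoulli with
   *p*ᵢ = 10^(−Qᵢ/10)), an exact binomial test against the error level
   of the flanking sites, and Bonferroni correction over candidate
   sites.
2. **Frequency clustering** (`clonaltree.clustering`) — exact 95%
   Clopper–Pearson intervals; cluster *seeds* are the mutations with
   non-overlapping or smallest intervals; remaining mutations join a
   seed in two steps (unambiguous interval overlap, then highest exact
   binomial probability under each cluster's pooled frequency
   *f* = Σrᵢ/Σnᵢ).
3. **Tree reconstruction** (`clonaltree.trees`) — dividing each cluster
   frequency by the lowest one yields the integer leaf counts
   N_tot = {N_ext, (N_int)ᵢ, …, 1}; a recursive algorithm enumerates
   every rooted full binary tree whose node leaf counts realise this
   combination.  The number of *candidate* trees for N_ext external
   nodes is the unlabeled-rooted-tree count (286 for N_ext = 9;
   12,826,228 for N_ext = 20), so finding that only one — or a handful
   of near-identical — compatible trees exist is highly informative,
   and the package quantifies exactly how unlikely compatibility is by
   chance by exhaustive enumeration of internal-value subsets.

Stability simulations (`clonaltree.robustness`: frequency perturbation
within the 95% CIs and random mutation deletion), a ground-truth
clonal-expansion simulator with a realistic sequencing error model
(`clonaltree.simulate`), and synthetic stand-ins for a four-adenoma
study cohort (`clonaltree.synthetic_cohort`) round out the package.

## Worked example

```python
from clonaltree import ProliferationModel
from clonaltree.synthetic_cohort import adenoma_profile

res = ProliferationModel(adenoma_profile("A2")).fit()
print(res.summary())
```

```
Proliferation-history reconstruction
====================================================
mutations:           56
clusters:            5
node combination:    {9, 6, 3, 2, 1}
external nodes:      9
candidate trees:     286
compatible trees:    1
----------------------------------------------------
 cluster  size  frequency  value  seed_ci_low  seed_ci_high  clonal
       1    30     0.5400      9       0.5169        0.5727    True
       2    10     0.3600      6       0.3332        0.3916   False
       3     6     0.1801      3       0.1489        0.1990   False
       4     5     0.1199      2       0.0943        0.1377   False
       5     5     0.0599      1       0.0478        0.0794   False
----------------------------------------------------
dominant branch (leaf counts, first tree): 9 > 6 > 3 > 1
unambiguous mutations on dominant branch: 71.4%
```

Reading the output: the 56 somatic mutations fall into five frequency
clusters.  The clonal cluster (54%, the tumor-cell content of the
sample) sets the root; dividing every cluster frequency by the lowest
(6%) gives the node combination {9, 6, 3, 2, 1}.  Of the 286 candidate
rooted trees on nine external nodes, exactly one realises that
combination — a tree whose dominant branch (9 → 6 → 3 → 1) carries
most of the mutation load, i.e. one subclone outgrew its siblings from
early in the expansion.  `res.trees[0]`, `res.to_newick(path)`,
`res.perturbation_study(...)` and `res.plot_clusters()` expose the
fitted objects.

The same analysis runs from the shell on extended pileup files:

```sh
clonaltree simulate --planted-ntot 5,3,2,1 --seed 7 --out-prefix sim/
clonaltree call --tumor sim/tumor.pileup.tsv --normal sim/normal.pileup.tsv --out calls.vcf
clonaltree cluster --calls calls.vcf --out clusters.json
clonaltree tree --clusters clusters.json --out trees/ --probability
```

The extended pileup is a TSV with one row per genomic site and one
`base:quality:strand:read_position:read_start` record per aligned call
(documented in `clonaltree.pileup_io`); calls are written as VCF v4.2
and trees as Newick with `L<leafcount>_M<mutations>` node labels.

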