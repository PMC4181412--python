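"""Model/Results layer tying the pipeline together.

:class:`ProliferationModel` is built from a somatic mutation profile (a
list of mutations or a DataFrame with ``r`` and ``n`` columns);
``fit()`` clusters the frequencies, derives the node combination and
enumerates the compatible proliferation trees, returning a
:class:`ProliferationResults` that carries the estimates and exposes the
stability simulations and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CallerConfig, SomaticMutation, call_variants, \
    subtract_germline
from .clustering import (MutationCluster, cluster_mutations,
                         expected_cluster_size, find_seeds,
                         with_confidence_intervals)
from .robustness import SimulationReport, deletion_study, perturbation_study
from .trees import (NodeCombination, ProliferationTree, assign_mutations,
                    combination_space, count_rooted_trees, node_combination)


class ProliferationModel:
    """Proliferation-history model for one tumor's mutation profile.

    Parameters
    ----------
    mutations
        Somatic mutations with variant count ``r`` and coverage ``n``.
        Frequencies must be cell fractions on a copy-neutral hemizygous
        region (no dosage correction is applied).
    coverage_values
        Optional coverage of every sequenced position (not only mutated
        ones), used for detection-corrected expected cluster sizes.
    level
        Confidence level of the binomial intervals that drive clustering.
    """

    def __init__(self, mutations: Sequence[SomaticMutation],
                 coverage_values: Sequence[int] | None = None,
                 level: float = 0.95) -> None:
        self.mutations = list(mutations)
        if not self.mutations:
            raise ValueError("the mutation profile is empty")
        self.coverage_values = (None if coverage_values is None
                                else np.asarray(coverage_values))
        self.level = level

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs
                       ) -> "ProliferationModel":
        """Build from a DataFrame with columns ``r`` and ``n``
        (optionally ``chrom``, ``pos``, ``ref``, ``alt``)."""
        muts = []
        for i, row in data.reset_index(drop=True).iterrows():
            r, n = int(row["r"]), int(row["n"])
            muts.append(SomaticMutation(
                chrom=str(row.get("chrom", "chr?")),
                pos=int(row.get("pos", i + 1)),
                ref_base=str(row.get("ref", "N")) or "N",
                alt_base=str(row.get("alt", "N")) or "N",
                r=r, n=n, frequency=r / n))
        return cls(muts, **kwargs)

    @classmethod
    def from_pileups(cls, tumor, normal=None,
                     window: tuple[int, int] = (20, 76),
                     config: CallerConfig | None = None,
                     **kwargs) -> "ProliferationModel":
        """Run the variant caller on tumor (and matched normal) pileups."""
        calls = call_variants(tumor, window, config)
        if normal is not None:
            calls = subtract_germline(calls, normal, config)
        cov = [c.coverage for c in tumor]
        kwargs.setdefault("coverage_values", cov)
        return cls(calls, **kwargs)

    def fit(self) -> "ProliferationResults":
        """Cluster the profile and reconstruct the compatible trees."""
        ms = with_confidence_intervals(self.mutations, self.level)
        seeds = find_seeds(ms)
        clusters = cluster_mutations(ms, seeds)
        combo = node_combination(clusters)
        from .trees import enumerate_compatible_trees

        trees = enumerate_compatible_trees(combo)
        for tree in trees:
            assign_mutations(tree, clusters)
        return ProliferationResults(model=self, clusters=clusters,
                                    combo=combo, trees=trees)


@dataclass
class ProliferationResults:
    """Fitted clusters, node combination and compatible trees."""

    model: ProliferationModel
    clusters: list[MutationCluster]
    combo: NodeCombination
    trees: list[ProliferationTree]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_ext(self) -> int:
        return self.combo.n_ext

    @property
    def n_possible_trees(self) -> int:
        """Count of candidate rooted trees for this many external nodes."""
        return count_rooted_trees(self.n_ext)

    def chance_probability(self) -> float:
        """Fraction of same-size internal-value subsets admitting a tree."""
        return combination_space(
            self.n_ext, len(self.combo.internal_values)).fraction

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        f_min = self.clusters[-1].f if self.clusters else np.nan
        for j, c in enumerate(sorted(self.clusters, key=lambda c: -c.f), 1):
            row = {
                "cluster": j, "size": c.size, "frequency": c.f,
                "value": int(np.floor(c.f / f_min + 0.5)),
                "seed_ci_low": c.seed.ci_low, "seed_ci_high": c.seed.ci_high,
                "clonal": c.is_clonal,
            }
            if self.model.coverage_values is not None:
                row["expected_size"] = expected_cluster_size(
                    c, self.model.coverage_values)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fit (statsmodels-style)."""
        lines = [
            "Proliferation-history reconstruction",
            "=" * 52,
            f"mutations:           {len(self.model.mutations)}",
            f"clusters:            {self.n_clusters}",
            f"node combination:    {self.combo}",
            f"external nodes:      {self.n_ext}",
            f"candidate trees:     {self.n_possible_trees}",
            f"compatible trees:    {len(self.trees)}",
            "-" * 52,
        ]
        table = self.cluster_table()
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(table.to_string(index=False))
        if self.trees:
            dom = [n.leaf_count for n in self.trees[0].dominant_branch]
            lines.append("-" * 52)
            lines.append(
                "dominant branch (leaf counts, first tree): "
                + " > ".join(map(str, dom)))
            lines.append(
                f"unambiguous mutations on dominant branch: "
                f"{self.dominant_branch_fraction():.1%}")
        return "\n".join(lines)

    def dominant_branch_fraction(self, tree_index: int = 0) -> float:
        """Share of all mutations unambiguously assigned to nodes of the
        dominant branch."""
        tree = self.trees[tree_index]
        assigned = sum(n.assigned_mutation_count
                       for n in tree.dominant_branch if not n.ambiguous)
        return assigned / len(self.model.mutations)

    # -- simulation ------------------------------------------------------
    def perturbation_study(self, fraction: float = 0.4,
                           iterations: int = 1000,
                           seed: int = 0) -> SimulationReport:
        return perturbation_study(self.model.mutations, fraction,
                                  iterations, seed)

    def deletion_study(self, fraction: float = 0.1,
                       iterations: int = 1000,
                       seed: int = 0) -> SimulationReport:
        return deletion_study(self.model.mutations, fraction,
                              iterations, seed)

    # -- output ----------------------------------------------------------
    def to_newick(self, path, tree_index: int = 0) -> None:
        from .pileup_io import write_newick

        write_newick(self.trees[tree_index], path)

    def plot_clusters(self, ax=None):
        """Frequency ladder with CIs, coloured by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = 0
        for j, c in enumerate(sorted(self.clusters, key=lambda c: -c.f)):
            members = sorted(c.members, key=lambda m: -m.frequency)
            xs = np.arange(x, x + len(members))
            ax.errorbar(
                xs, [m.frequency for m in members],
                yerr=[[m.frequency - m.ci_low for m in members],
                      [m.ci_high - m.frequency for m in members]],
                fmt=".", ms=3, lw=0.5, label=f"cluster {j + 1} (f={c.f:.3f})")
            x += len(members)
        ax.set_xlabel("mutation (grouped by cluster)")
        ax.set_ylabel("variant allele frequency")
        ax.legend(fontsize=7)
        return ax
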