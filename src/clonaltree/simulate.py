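"""Ground-truth clonal-expansion simulator and pileup renderer.

The generator produces a tumor with a known proliferation tree and known
per-mutation cell fractions, then renders tumor and matched-normal
extended pileups under an error model emulating deep targeted capture
sequencing: overdispersed (negative-binomial) coverage around ~300x,
phred-scaled per-call miscalls, elevated error at the read ends outside
the usable window, PCR-duplicate read starts, and configurable tumor
purity.  Every downstream module is therefore testable against planted
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pileup_io import PileupColumn
from .trees import (NodeCombination, ProliferationTree, TreeNode,
                    enumerate_compatible_trees)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PlantedMutation:
    pos: int
    node: TreeNode
    frequency: float  # fraction of tumor cells carrying it
    ref_base: str = "A"
    alt_base: str = "G"


@dataclass
class SyntheticTumor:
    """A simulated clonal expansion with per-mutation truth."""

    tree: ProliferationTree
    mutations: list[PlantedMutation]
    genome_length: int
    germline_positions: list[int] = field(default_factory=list)
    ref_sequence: np.ndarray | None = None  # shared by tumor/normal renders

    @property
    def n_ext(self) -> int:
        return self.tree.n_ext

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame({
            "pos": [m.pos for m in self.mutations],
            "ref": [m.ref_base for m in self.mutations],
            "alt": [m.alt_base for m in self.mutations],
            "frequency": [m.frequency for m in self.mutations],
            "node_leaf_count": [m.node.leaf_count for m in self.mutations],
        })


@dataclass
class ErrorModel:
    """Sequencing error model for pileup rendering.

    The per-call miscall probability is ``10**(-Q/10)`` for the drawn
    quality Q, multiplied by ``end_error_multiplier`` when the call's
    read position falls outside ``usable_window`` (emulating the error
    pile-up at read ends).  Coverage is negative-binomial with the given
    mean and dispersion (variance = mean + mean^2/dispersion).  Purity is
    the fraction of tumor cells in the sequenced mix; the paper's setting
    is a copy-neutral hemizygous chromosome, so no dosage correction is
    applied anywhere.
    """

    mean_coverage: float = 300.0
    dispersion: float = 8.0
    read_length: int = 76
    usable_window: tuple[int, int] = (20, 76)
    end_error_multiplier: float = 3.0
    qualities: tuple[int, ...] = (37, 33, 30, 22, 12)
    quality_weights: tuple[float, ...] = (0.55, 0.2, 0.15, 0.07, 0.03)
    duplicate_rate: float = 0.1
    purity: float = 1.0
    error_scale: float = 1.0  # 0 switches sequencing error off

    def draw_coverage(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.dispersion / (self.dispersion + self.mean_coverage)
        return rng.negative_binomial(self.dispersion, p, size=size)


def _grow_planted(combo: NodeCombination) -> ProliferationTree:
    trees = enumerate_compatible_trees(combo)
    if not trees:
        raise ValueError(f"no tree realises the planted combination {combo}")
    return trees[0]


class _Cell:
    __slots__ = ("kids",)

    def __init__(self) -> None:
        self.kids: list["_Cell"] = []


def _grow_stochastic(n_ext_target: int, death_rate: float,
                     rng: np.random.Generator) -> ProliferationTree:
    """Branching process: synchronous divisions, per-daughter death.

    The observed proliferation tree is the genealogy restricted to
    surviving lineages, with single-survivor chains collapsed (a division
    where one daughter line dies does not increase the population and
    leaves no branching in the record).
    """
    while True:  # retry on total extinction
        root = _Cell()
        alive: list[_Cell] = [root]
        generations = 0
        while 0 < len(alive) < n_ext_target and generations < 64:
            nxt: list[_Cell] = []
            for cell in alive:
                for _ in range(2):
                    if rng.random() < death_rate:
                        continue
                    kid = _Cell()
                    cell.kids.append(kid)
                    nxt.append(kid)
            alive = nxt
            generations += 1
        if len(alive) >= n_ext_target:
            break

    def observe(cell: _Cell) -> TreeNode | None:
        obs = [o for o in (observe(k) for k in cell.kids) if o is not None]
        if not cell.kids:
            return TreeNode(leaf_count=1)
        if not obs:
            return None  # whole subtree went extinct
        if len(obs) == 1:
            return obs[0]  # collapse the non-branching division
        node = obs[0]
        for other in obs[1:]:  # fold >2 survivors pairwise (never happens
            node = TreeNode(leaf_count=node.leaf_count + other.leaf_count,
                            children=(node, other))  # for binary division)
        return node

    observed = observe(root)
    assert observed is not None

    def fill(node: TreeNode) -> int:
        if not node.children:
            node.leaf_count = 1
            return 1
        node.leaf_count = sum(fill(k) for k in node.children)
        return node.leaf_count

    fill(observed)
    return ProliferationTree(root=observed)


def simulate_proliferation(n_ext_target: int | None = None,
                           planted: NodeCombination | Sequence[int] | None = None,
                           mutation_rate: float = 8.0,
                           death_rate: float = 0.2,
                           genome_length: int = 3000,
                           n_germline: int = 5,
                           seed: int = 0) -> SyntheticTumor:
    """Simulate a clonal expansion with known mutation frequencies.

    In planted mode (``planted`` given, either a :class:`NodeCombination`
    or the full value multiset, e.g. ``[5, 3, 2, 1]``) the tree realises
    the requested combination exactly.  In stochastic mode a binary tree
    grows with per-division lineage death until ``n_ext_target`` lineages
    survive.  Per-node new-mutation counts are Poisson(``mutation_rate``);
    each mutation's true cell fraction is its node's leaf count over the
    total leaf count, so descendants never exceed their ancestors.
    """
    rng = np.random.default_rng(seed)
    if planted is not None:
        if not isinstance(planted, NodeCombination):
            vals = sorted(planted, reverse=True)
            planted = NodeCombination(
                n_ext=vals[0],
                internal_values=tuple(v for v in vals if 1 < v < vals[0]))
        tree = _grow_planted(planted)
    else:
        if n_ext_target is None:
            raise ValueError("either planted or n_ext_target is required")
        tree = _grow_stochastic(n_ext_target, death_rate, rng)

    n_ext = tree.n_ext
    sites = rng.choice(np.arange(1, genome_length + 1),
                       size=min(genome_length, 4096), replace=False)
    cursor = 0
    mutations: list[PlantedMutation] = []
    nodes = tree.nodes()
    for node in nodes:
        k = rng.poisson(mutation_rate) if mutation_rate > 0 else 0
        for _ in range(k):
            if cursor >= len(sites):
                raise ValueError("genome too short for the mutation load")
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            mutations.append(PlantedMutation(
                pos=int(sites[cursor]), node=node,
                frequency=node.leaf_count / n_ext,
                ref_base=str(ref), alt_base=str(alt)))
            cursor += 1
    germline = [int(p) for p in sites[cursor:cursor + n_germline]]
    mutations.sort(key=lambda m: m.pos)
    ref = rng.choice(_BASES, size=genome_length)
    for m in mutations:
        ref[m.pos - 1] = m.ref_base
    return SyntheticTumor(tree=tree, mutations=mutations,
                          genome_length=genome_length,
                          germline_positions=germline, ref_sequence=ref)


def render_pileup(tumor: SyntheticTumor,
                  model: ErrorModel | None = None,
                  normal: bool = False,
                  seed: int = 0) -> list[PileupColumn]:
    """Render a tumor (or matched-normal) extended pileup.

    Per position the coverage is drawn from the model's overdispersed
    distribution; each call carries the true allele with probability
    (cell fraction x purity) at mutated sites (reference plus germline
    variants only when ``normal``), then is miscalled with its
    phred-implied probability times the read-end multiplier.  Read starts
    emulate fragment placement with a PCR-duplicate excess.
    """
    model = model or ErrorModel()
    rng = np.random.default_rng(seed)
    if tumor.ref_sequence is not None:
        ref = tumor.ref_sequence.copy()
    else:
        ref = np.random.default_rng(tumor.genome_length).choice(
            _BASES, size=tumor.genome_length)
        for m in tumor.mutations:
            ref[m.pos - 1] = m.ref_base
    by_pos = {m.pos: m for m in tumor.mutations}
    germline = set(tumor.germline_positions)

    coverages = model.draw_coverage(rng, tumor.genome_length)
    lo, hi = model.usable_window
    quals_pool = np.array(model.qualities)
    qw = np.array(model.quality_weights, dtype=float)
    qw = qw / qw.sum()
    columns: list[PileupColumn] = []
    for pos in range(1, tumor.genome_length + 1):
        n = int(coverages[pos - 1])
        if n == 0:
            columns.append(PileupColumn(
                "chrS", pos, str(ref[pos - 1]), np.empty(0, dtype="U1"),
                np.empty(0, dtype=int), np.empty(0, dtype=bool),
                np.empty(0, dtype=int), np.empty(0, dtype=int)))
            continue
        ref_base = str(ref[pos - 1])
        mut = by_pos.get(pos)
        if pos in germline:
            # hemizygous germline variant: carried by every cell
            alt_base, alt_fraction = ("T" if ref_base != "T" else "C"), 1.0
        elif mut is not None and not normal:
            alt_base, alt_fraction = mut.alt_base, mut.frequency * model.purity
        else:
            alt_base, alt_fraction = ref_base, 0.0

        true_alt = rng.random(n) < alt_fraction
        quals = rng.choice(quals_pool, size=n, p=qw)
        read_pos = rng.integers(1, model.read_length + 1, size=n)
        p_err = model.error_scale * 10.0 ** (-0.1 * quals)
        outside = (read_pos < lo) | (read_pos > hi)
        p_err = np.where(outside, np.minimum(
            0.75, p_err * model.end_error_multiplier), p_err)
        miscall = rng.random(n) < p_err

        bases = np.where(true_alt, alt_base, ref_base).astype("U1")
        if miscall.any():
            idx = np.flatnonzero(miscall)
            shift = rng.integers(1, 4, size=len(idx))
            codes = np.searchsorted(_BASES, bases[idx])
            bases[idx] = _BASES[(codes + shift) % 4]
        forward = rng.random(n) < 0.5
        starts = pos - read_pos + 1
        if model.duplicate_rate > 0 and n > 1:
            dup = rng.random(n) < model.duplicate_rate
            donors = rng.integers(0, n, size=n)
            starts = np.where(dup, starts[donors], starts)
            read_pos = np.where(dup, np.minimum(model.read_length,
                                                pos - starts + 1), read_pos)
        columns.append(PileupColumn("chrS", pos, ref_base, bases, quals,
                                    forward, read_pos, starts))
    return columns
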