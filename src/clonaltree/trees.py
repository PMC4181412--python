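"""Proliferation-tree reconstruction from mutation-cluster frequencies.

A monoclonal expansion is modelled as a rooted full binary tree whose
leaves are the surviving lineages of the final tumor population.  Every
node carries a *leaf count* -- the number of leaves below it -- and the
mutations that arose in the corresponding cell are present in exactly
that many of the surviving lineages.  Dividing each cluster's mean
frequency by the lowest cluster's mean frequency therefore converts the
frequency ladder into integer leaf counts:

* ``n_ext`` = f(highest cluster)/f(lowest cluster): the root's leaf count;
* each internal cluster maps to ``f_i/f(lowest)``: leaf counts of
  internal nodes;
* the lowest cluster maps to 1: the leaves.

A tree is *compatible* with the node combination ``N_tot`` when every
node's leaf count is one of the admissible values (the combination plus
1) and every internal value is realised by at least as many nodes as its
multiplicity in the combination.  The recursion that enumerates the
compatible trees splits each value v into unordered pairs (a, b) of
admissible values with a + b = v; values are reusable across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, prod
from typing import Iterable, Sequence

import numpy as np

from .clustering import MutationCluster


# ---------------------------------------------------------------------------
# Node combinations

@dataclass(frozen=True)
class NodeCombination:
    """The multiset {n_ext, internal values..., 1} of leaf counts."""

    n_ext: int
    internal_values: tuple[int, ...]  # sorted, may contain repeats

    def __post_init__(self) -> None:
        if self.n_ext < 1:
            raise ValueError("n_ext must be >= 1")
        for v in self.internal_values:
            if not 1 < v < self.n_ext:
                raise ValueError(
                    f"internal value {v} outside (1, {self.n_ext})")
        object.__setattr__(self, "internal_values",
                           tuple(sorted(self.internal_values)))

    @property
    def values(self) -> tuple[int, ...]:
        """Full multiset including n_ext and the implicit 1."""
        if self.n_ext == 1:
            return (1,)
        return tuple(sorted((self.n_ext, *self.internal_values, 1),
                            reverse=True))

    def signature(self) -> tuple[int, ...]:
        """Canonical hashable form (used by the deletion study)."""
        return self.values

    def __str__(self) -> str:
        return "{" + ", ".join(str(v) for v in self.values) + "}"


def node_combination(clusters: Sequence[MutationCluster] | Sequence[float],
                     ) -> NodeCombination:
    """Derive the node combination from cluster mean frequencies.

    Each cluster frequency is divided by the lowest cluster frequency and
    rounded to the nearest integer; the highest cluster gives ``n_ext``
    and the lowest maps to 1.  Accepts clusters or raw frequencies.
    """
    freqs = sorted(
        (c.f if isinstance(c, MutationCluster) else float(c))
        for c in clusters)
    if not freqs:
        raise ValueError("at least one cluster required")
    f_min = freqs[0]
    if f_min <= 0:
        raise ValueError("lowest cluster frequency must be positive")
    ratios = [int(np.floor(f / f_min + 0.5)) for f in freqs]
    if any(v < 1 for v in ratios):
        raise ValueError("a cluster frequency rounded below 1")
    n_ext = ratios[-1]
    internal = tuple(v for v in ratios[:-1] if v > 1 and v < n_ext)
    return NodeCombination(n_ext=n_ext, internal_values=internal)


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    """Node of a proliferation tree (leaf_count = descendant leaves)."""

    leaf_count: int
    children: tuple["TreeNode", ...] = ()
    assigned_cluster: MutationCluster | None = None
    assigned_mutation_count: int = 0
    ambiguous: bool = False

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def signature(self):
        """Canonical nested-tuple form, invariant to sibling order."""
        if not self.children:
            return (1,)
        kids = sorted((c.signature() for c in self.children))
        return (self.leaf_count, kids[0], kids[1])


@dataclass
class ProliferationTree:
    """A rooted full binary proliferation tree."""

    root: TreeNode
    dominant_branch: tuple[TreeNode, ...] = ()

    @property
    def n_ext(self) -> int:
        return self.root.leaf_count

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.children]

    def signature(self):
        return self.root.signature()

    def validate(self) -> None:
        for node in self.root.walk():
            if node.children:
                if len(node.children) != 2:
                    raise ValueError("internal node without two children")
                if node.leaf_count != sum(c.leaf_count
                                          for c in node.children):
                    raise ValueError("leaf counts not additive")
            elif node.leaf_count != 1:
                raise ValueError("leaf with leaf_count != 1")


def _from_signature(sig) -> TreeNode:
    if len(sig) == 1:
        return TreeNode(leaf_count=1)
    return TreeNode(leaf_count=sig[0],
                    children=(_from_signature(sig[1]),
                              _from_signature(sig[2])))


def enumerate_compatible_trees(combo: NodeCombination,
                               ) -> list[ProliferationTree]:
    """All full binary trees compatible with the node combination.

    Recursive descent from the root: a node with value v > 1 splits into
    an unordered pair (a, b) with a + b = v, both drawn from the
    admissible value set {n_ext} | internal values | {1} (values are
    reusable; the combination's multiplicities only impose lower bounds
    on how often each internal value must appear).  Trees are returned in
    canonical form, deduplicated up to sibling order; the empty list is a
    valid outcome meaning no tree realises the combination.
    """
    from collections import Counter

    need = Counter(combo.internal_values)
    V = sorted(set(combo.internal_values) | {1, combo.n_ext})

    memo: dict[int, list] = {}

    def subtrees(v: int) -> list:
        if v in memo:
            return memo[v]
        if v == 1:
            out = [(1,)]
        else:
            out = []
            seen = set()
            for a in V:
                if a > v // 2:
                    break
                b = v - a
                if b not in V or a >= v or b >= v:
                    continue
                for ta in subtrees(a):
                    for tb in subtrees(b):
                        lo, hi = sorted((ta, tb))
                        sig = (v, lo, hi)
                        if sig not in seen:
                            seen.add(sig)
                            out.append(sig)
        memo[v] = out
        return out

    def value_counts(sig, counts: Counter) -> None:
        counts[sig[0]] += 1
        if len(sig) > 1:
            value_counts(sig[1], counts)
            value_counts(sig[2], counts)

    trees = []
    for sig in subtrees(combo.n_ext):
        counts: Counter = Counter()
        value_counts(sig, counts)
        if all(counts[v] >= m for v, m in need.items()):
            trees.append(ProliferationTree(root=_from_signature(sig)))
    return trees


def compatible_tree_exists(n_ext: int,
                           internal_values: Sequence[int]) -> bool:
    """Fast existence check for a compatible tree (bitmask coverage DP).

    Equivalent to ``len(enumerate_compatible_trees(...)) > 0`` for
    distinct internal values but avoids materialising the trees; used by
    the exhaustive chance-probability enumeration.  (The no-internal-
    cluster convention -- trivial success -- is applied one level up, in
    :func:`combination_space`.)
    """
    vals = sorted(set(internal_values))
    V = set(vals) | {1, n_ext}
    idx = {v: i for i, v in enumerate(vals)}
    full = (1 << len(vals)) - 1
    memo: dict[int, tuple[int, ...]] = {}

    def masks(v: int) -> tuple[int, ...]:
        if v in memo:
            return memo[v]
        if v == 1:
            out: tuple[int, ...] = (0,)
        else:
            own = 1 << idx[v] if v in idx else 0
            acc = set()
            for a in sorted(V):
                if a > v // 2:
                    break
                b = v - a
                if b not in V or a >= v or b >= v:
                    continue
                for ma in masks(a):
                    for mb in masks(b):
                        acc.add(own | ma | mb)
            # prune to maximal masks
            kept: list[int] = []
            for cand in sorted(acc, key=lambda m: -bin(m).count("1")):
                if not any(cand | k == k for k in kept):
                    kept.append(cand)
            out = tuple(kept)
        memo[v] = out
        return out

    return any(m == full for m in masks(n_ext))


# ---------------------------------------------------------------------------
# Tree counting

@lru_cache(maxsize=None)
def _rooted_tree_counts(n_max: int) -> tuple[int, ...]:
    # unlabeled rooted trees on n nodes, by the Euler-transform convolution
    a = [0] * (n_max + 1)
    if n_max >= 1:
        a[1] = 1
    for n in range(1, n_max):
        s = 0
        for k in range(1, n + 1):
            divisor_sum = sum(d * a[d] for d in range(1, k + 1) if k % d == 0)
            s += divisor_sum * a[n - k + 1]
        a[n + 1] = s // n  # the convolution sum is always divisible by n
    return tuple(a)


def count_rooted_trees(n: int) -> int:
    """Number of unlabeled rooted trees on n nodes (exact integer).

    This is the count of candidate proliferation histories for a tumor
    whose root subtends n external nodes; it grows roughly like 2.956**n
    and is computed by the standard convolution recurrence in exact
    integer arithmetic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _rooted_tree_counts(n)[n]


# ---------------------------------------------------------------------------
# Chance probability of tree existence

@dataclass(frozen=True)
class CombinationSpace:
    """Exhaustive compatibility census for one sample.

    n admissible internal values (integers in [2, n_ext - 1]), c internal
    clusters, ``total`` = C(n, c) distinct value subsets, ``successes`` of
    which admit at least one compatible tree.
    """

    n_ext: int
    c: int
    successes: int
    total: int

    @property
    def fraction(self) -> float:
        return self.successes / self.total if self.total else 1.0


def combination_space(n_ext: int, c: int) -> CombinationSpace:
    """Enumerate all C(n_ext-2, c) internal-value subsets of one sample."""
    n = n_ext - 2
    if c < 0 or c > n:
        raise ValueError(f"c={c} outside [0, {n}] for n_ext={n_ext}")
    if c == 0:
        # no internal cluster constrains the tree shape: trivially realisable
        return CombinationSpace(n_ext, 0, successes=1, total=1)
    successes = sum(
        compatible_tree_exists(n_ext, subset)
        for subset in combinations(range(2, n_ext), c))
    return CombinationSpace(n_ext, c, successes=successes, total=comb(n, c))


def tree_existence_probability(samples: Sequence[tuple[int, int]],
                               ) -> tuple[float, list[CombinationSpace]]:
    """Chance probability that every sample admits a compatible tree.

    For each (n_ext, c) the internal-value subsets are enumerated
    exhaustively and the fraction admitting a compatible tree is
    recorded; the joint probability that all samples would admit a tree
    had their internal values been drawn at random is the product of the
    per-sample fractions.  Returns (joint probability, per-sample census).
    The result is invariant under sample order.
    """
    spaces = [combination_space(n_ext, c) for n_ext, c in samples]
    return prod(s.fraction for s in spaces), spaces


# ---------------------------------------------------------------------------
# Mutation assignment

class TreeAssignmentError(ValueError):
    """A cluster's value matches no node of the tree."""


def assign_mutations(tree: ProliferationTree,
                     clusters: Sequence[MutationCluster],
                     ) -> ProliferationTree:
    """Attach clusters to the tree nodes realising their values.

    Each cluster (with integer value = rounded frequency ratio) attaches
    to the nodes whose leaf count equals its value.  A cluster matching
    exactly one node is assigned unambiguously and contributes its
    mutation count to that node; a cluster matching several nodes is
    flagged ambiguous on all of them.  The lowest cluster (value 1)
    attaches to the leaves collectively and is therefore ambiguous
    whenever the tree has more than one leaf.  The dominant branch is the
    root-to-leaf path with the highest cumulative unambiguously assigned
    mutation count.
    """
    ordered = sorted(clusters, key=lambda c: -c.f)
    f_min = ordered[-1].f
    if f_min <= 0:
        raise ValueError("lowest cluster frequency must be positive")
    values = [int(np.floor(c.f / f_min + 0.5)) for c in ordered]
    nodes = tree.nodes()
    for node in nodes:
        node.assigned_cluster = None
        node.assigned_mutation_count = 0
        node.ambiguous = False
    for cluster, value in zip(ordered, values):
        matches = [n for n in nodes if n.leaf_count == value]
        if not matches:
            raise TreeAssignmentError(
                f"cluster value {value} not realised by any node")
        if len(matches) == 1:
            matches[0].assigned_cluster = cluster
            matches[0].assigned_mutation_count = cluster.size
        else:
            for n in matches:
                n.ambiguous = True
                n.assigned_cluster = cluster

    def best_path(node: TreeNode) -> tuple[int, tuple[TreeNode, ...]]:
        own = 0 if node.ambiguous else node.assigned_mutation_count
        if not node.children:
            return own, (node,)
        scored = [best_path(c) for c in node.children]
        score, path = max(scored, key=lambda t: t[0])
        return own + score, (node, *path)

    _, path = best_path(tree.root)
    tree.dominant_branch = path
    return tree
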