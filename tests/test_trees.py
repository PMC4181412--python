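from collections import Counter
from itertools import combinations
from math import comb

import numpy as np
import pytest

from clonaltree.clustering import MutationCluster
from clonaltree.calling import SomaticMutation
from clonaltree.trees import (CombinationSpace, NodeCombination,
                              TreeAssignmentError, assign_mutations,
                              combination_space, compatible_tree_exists,
                              count_rooted_trees, enumerate_compatible_trees,
                              node_combination, tree_existence_probability)


# ---------------------------------------------------------------------------
# Brute-force oracles

def _all_full_binary_trees(leaves):
    """Every unordered full binary tree with the given number of leaves."""
    if leaves == 1:
        return [(1,)]
    out = set()
    for a in range(1, leaves // 2 + 1):
        b = leaves - a
        for ta in _all_full_binary_trees(a):
            for tb in _all_full_binary_trees(b):
                lo, hi = sorted((ta, tb))
                out.add((leaves, lo, hi))
    return sorted(out)


def _values(sig, acc=None):
    acc = Counter() if acc is None else acc
    acc[sig[0]] += 1
    if len(sig) > 1:
        _values(sig[1], acc)
        _values(sig[2], acc)
    return acc


def _brute_force_compatible(n_ext, internal):
    """Filter every full binary tree for the compatibility conditions."""
    need = Counter(internal)
    allowed = set(internal) | {1, n_ext}
    out = []
    for sig in _all_full_binary_trees(n_ext):
        counts = _values(sig)
        if set(counts) <= allowed and \
                all(counts[v] >= m for v, m in need.items()):
            out.append(sig)
    return sorted(out)


def _all_rooted_trees(n):
    """Every unlabeled rooted tree on n nodes, as canonical tuples."""
    if n == 1:
        return {()}
    out = set()
    # children form a multiset of rooted trees with sizes summing to n-1
    def extend(remaining, min_size, chosen):
        if remaining == 0:
            out.add(tuple(sorted(chosen)))
            return
        for size in range(min_size, remaining + 1):
            for sub in _all_rooted_trees(size):
                if not chosen or (size, sub) >= chosen[-1][:1] + (sub,):
                    pass
                extend(remaining - size, size, chosen + [(size, sub)])

    extend(n - 1, 1, [])
    return out


# ---------------------------------------------------------------------------
# Node combination

def test_single_cluster_maps_to_one():
    combo = node_combination([0.4])
    assert combo.n_ext == 1 and combo.values == (1,)


def test_worked_ratio_ladder():
    combo = node_combination([0.50, 0.30, 0.20, 0.10])
    assert combo.values == (5, 3, 2, 1)


def test_node_combination_rounding():
    combo = node_combination([0.52, 0.29, 0.21, 0.102])
    assert combo.values == (5, 3, 2, 1)


def test_node_combination_requires_positive_minimum():
    with pytest.raises(ValueError):
        node_combination([0.5, 0.0])


def test_published_external_node_counts():
    from clonaltree.synthetic_cohort import (CLONAL_FREQUENCY, CLUSTER_VALUES,
                                             SAMPLES)

    expected = {"A1": 15, "A2": 9, "A3": 20, "A4": 14}
    for sample in SAMPLES:
        vals = CLUSTER_VALUES[sample]
        freqs = [v * CLONAL_FREQUENCY[sample] / vals[0] for v in vals]
        assert node_combination(freqs).n_ext == expected[sample]


# ---------------------------------------------------------------------------
# Enumeration

def test_cherry_is_unique_tree():
    trees = enumerate_compatible_trees(NodeCombination(2, ()))
    assert len(trees) == 1
    assert trees[0].signature() == (2, (1,), (1,))


def test_worked_topology_is_unique():
    trees = enumerate_compatible_trees(NodeCombination(5, (3, 2)))
    assert len(trees) == 1
    # root 5 -> (2, 3); 3 -> (1, 2); both 2s -> (1, 1)
    assert trees[0].signature() == \
        (5, (2, (1,), (1,)), (3, (1,), (2, (1,), (1,))))
    for tree in trees:
        tree.validate()


def test_enumeration_matches_brute_force_everywhere():
    rng = np.random.default_rng(1)
    cases = [(n_ext, tuple(sorted(sub)))
             for n_ext in range(2, 9)
             for _ in range(6)
             for sub in [rng.choice(range(2, max(3, n_ext)),
                                    size=rng.integers(0, min(4, n_ext - 1)),
                                    replace=False)]
             if all(1 < v < n_ext for v in sub)]
    cases += [(5, (3, 2)), (8, (4, 2)), (7, (2, 3, 5)), (6, ())]
    for n_ext, internal in cases:
        combo = NodeCombination(n_ext, internal)
        mine = sorted(t.signature()
                      for t in enumerate_compatible_trees(combo))
        oracle = _brute_force_compatible(n_ext, internal)
        assert mine == oracle, (n_ext, internal)
        # the fast existence check agrees too
        assert compatible_tree_exists(n_ext, tuple(internal)) == bool(oracle)


def test_tree_invariants_on_enumerated_trees():
    for tree in enumerate_compatible_trees(NodeCombination(9, (6, 3, 2))):
        tree.validate()
        for node in tree.nodes():
            if node.children:
                assert node.leaf_count == sum(
                    c.leaf_count for c in node.children)


# ---------------------------------------------------------------------------
# Counting

def test_rooted_tree_count_small_values_vs_exhaustive():
    for n in range(1, 9):
        assert count_rooted_trees(n) == len(_all_rooted_trees(n))


def test_rooted_tree_count_published_values():
    assert count_rooted_trees(9) == 286
    assert count_rooted_trees(14) == 32_973
    assert count_rooted_trees(15) == 87_811
    assert count_rooted_trees(20) == 12_826_228


def test_rooted_tree_count_strictly_increasing():
    counts = [count_rooted_trees(n) for n in range(3, 25)]
    assert all(a < b for a, b in zip(counts, counts[1:]))
    with pytest.raises(ValueError):
        count_rooted_trees(0)


# ---------------------------------------------------------------------------
# Chance probability

def test_combination_space_trivial_for_no_internal_clusters():
    space = combination_space(12, 0)
    assert space.successes == 1 and space.total == 1
    assert space.fraction == 1.0


def test_combination_space_n5_c1_exhaustive():
    # internal values 2, 3, 4 each fail to decompose a 5-leaf root
    space = combination_space(5, 1)
    assert (space.successes, space.total) == (0, 3)
    for v in (2, 3, 4):
        assert not compatible_tree_exists(5, (v,))


def test_combination_space_against_enumeration_oracle():
    n_ext, c = 9, 3
    successes = sum(
        bool(enumerate_compatible_trees(NodeCombination(n_ext, sub)))
        for sub in combinations(range(2, n_ext), c))
    space = combination_space(n_ext, c)
    assert space.successes == successes
    assert space.total == comb(n_ext - 2, c)


def test_probability_invariant_under_sample_order():
    samples = [(9, 3), (7, 2), (6, 1)]
    p1, _ = tree_existence_probability(samples)
    p2, _ = tree_existence_probability(samples[::-1])
    assert p1 == pytest.approx(p2)


def test_probability_rejects_too_many_clusters():
    with pytest.raises(ValueError):
        tree_existence_probability([(5, 4)])


# ---------------------------------------------------------------------------
# Mutation assignment

def _cluster(f, size):
    members = []
    for i in range(size):
        n = 1000
        r = round(f * n)
        m = SomaticMutation(chrom="c", pos=i + int(f * 1e6), ref_base="A",
                            alt_base="T", r=r, n=n, frequency=f)
        members.append(m)
    cl = MutationCluster(seed=members[0], members=members)
    cl.f = f
    return cl


def test_assignment_unique_values_all_unambiguous():
    # ladder {3, 2, 1}: the single tree (1,(1,1)) realises 3 and 2 once
    clusters = [_cluster(0.3, 10), _cluster(0.2, 5), _cluster(0.1, 3)]
    [tree] = enumerate_compatible_trees(node_combination(clusters))
    assign_mutations(tree, clusters)
    internal = [n for n in tree.nodes() if n.children]
    assert all(not n.ambiguous for n in internal)
    assert sum(n.assigned_mutation_count for n in internal) == 15


def test_assignment_flags_repeated_values_ambiguous():
    clusters = [_cluster(0.5, 8), _cluster(0.3, 4),
                _cluster(0.2, 4), _cluster(0.1, 4)]
    [tree] = enumerate_compatible_trees(node_combination(clusters))
    # value 2 is realised by two nodes of the {5,3,2,1} tree
    assign_mutations(tree, clusters)
    twos = [n for n in tree.nodes() if n.leaf_count == 2]
    assert len(twos) == 2
    assert all(n.ambiguous for n in twos)
    root = tree.root
    assert root.assigned_mutation_count == 8 and not root.ambiguous


def test_assignment_dominant_branch_accumulates_mutations():
    clusters = [_cluster(0.5, 100), _cluster(0.3, 40),
                _cluster(0.2, 10), _cluster(0.1, 5)]
    [tree] = enumerate_compatible_trees(node_combination(clusters))
    assign_mutations(tree, clusters)
    branch = tree.dominant_branch
    assert branch[0] is tree.root
    assert branch[-1].leaf_count == 1
    # the 3-node (40 mutations, unambiguous) lies on the dominant branch
    assert any(n.leaf_count == 3 for n in branch)


def test_assignment_error_on_unrealised_value():
    from clonaltree.trees import ProliferationTree, TreeNode

    cherry = ProliferationTree(root=TreeNode(
        leaf_count=2, children=(TreeNode(1), TreeNode(1))))
    clusters = [_cluster(0.5, 3), _cluster(0.25, 2), _cluster(0.125, 2)]
    with pytest.raises(TreeAssignmentError):
        assign_mutations(cherry, clusters)
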