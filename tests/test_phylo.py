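"""Phylogenetic diversity: parsing, pruning, branch abundances, Hill numbers."""

import numpy as np
import pytest

from divgrad import (
    branch_abundances,
    hill_phylo,
    hill_taxonomic,
    parse_newick,
    prune_to,
)
from divgrad.phylo import tip_labels

from conftest import random_abundances


def _random_tree(rng, n_tips):
    """Random rooted binary tree with uniform branch lengths (newick built
    by repeatedly joining subtrees)."""
    frags = [f"L{i}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a}:{rng.uniform(0.1, 2.0):.6f},"
                     f"{b}:{rng.uniform(0.1, 2.0):.6f})")
    return parse_newick(frags[0] + ";")


def _faith_pd_bruteforce(tree, p):
    """Sum of branch lengths on paths from the root to positive-abundance
    tips (each branch counted once)."""
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = {lf.taxon.label for lf in node.leaf_iter()}
        if any(p.get(t, 0) > 0 for t in tips):
            total += node.edge.length
    return total


# ---------------------------------------------------------------------------
# parsing

def test_parse_worked_tree(worked_tree):
    assert sorted(tip_labels(worked_tree)) == ["A", "B", "C"]
    edges = [nd.edge.length for nd in worked_tree.preorder_node_iter()
             if nd.parent_node is not None]
    assert sorted(edges) == [1, 1, 1, 2]
    depths = {lf.taxon.label: lf.distance_from_root()
              for lf in worked_tree.leaf_node_iter()}
    assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}


def test_parse_errors():
    with pytest.raises(ValueError):
        parse_newick("((A:1,B:1):1,C:2)")  # missing semicolon
    with pytest.raises(ValueError):
        parse_newick("((A:1,B),C:2);")  # missing branch length


def test_quoted_labels_preserved():
    tree = parse_newick("(('Inga edulis':1,B:1):1,C:2);")
    assert "Inga edulis" in tip_labels(tree)


# ---------------------------------------------------------------------------
# pruning

def test_prune_collapses_unbranched(worked_tree):
    pruned = prune_to(worked_tree, {"A", "C"})
    depths = {lf.taxon.label: lf.distance_from_root()
              for lf in pruned.leaf_node_iter()}
    assert depths == {"A": 2.0, "C": 2.0}
    assert len(list(pruned.leaf_node_iter())) == 2


def test_prune_identity(worked_tree):
    pruned = prune_to(worked_tree, {"A", "B", "C"})
    lens = sorted(nd.edge.length for nd in pruned.preorder_node_iter()
                  if nd.parent_node is not None)
    assert lens == [1, 1, 1, 2]


def test_prune_single_tip(worked_tree):
    pruned = prune_to(worked_tree, {"A"})
    (leaf,) = pruned.leaf_node_iter()
    assert leaf.distance_from_root() == pytest.approx(2.0)


def test_prune_missing_taxon(worked_tree):
    with pytest.raises(KeyError):
        prune_to(worked_tree, {"A", "Zzz"})


def test_prune_consistency_with_zero_abundance(rng):
    """Hill numbers on the pruned-to-support tree equal those on the full
    tree where the extra tips simply carry zero abundance."""
    for _ in range(20):
        tree = _random_tree(rng, int(rng.integers(5, 15)))
        labels = tip_labels(tree)
        support = list(rng.choice(labels, size=3, replace=False))
        p = dict(zip(support, random_abundances(rng, n=3)))
        bas_full = branch_abundances(tree, p)
        bas_pruned = branch_abundances(prune_to(tree, support), p)
        for q in (0.0, 0.7, 1.0, 2.0):
            m1, t1 = hill_phylo(bas_full, q)
            m2, t2 = hill_phylo(bas_pruned, q)
            assert m1 == pytest.approx(m2, abs=1e-9)
            assert t1 == pytest.approx(t2, abs=1e-9)


# ---------------------------------------------------------------------------
# branch abundances

def test_branch_abundances_worked(worked_tree):
    bas = branch_abundances(worked_tree, {"A": 0.25, "B": 0.25, "C": 0.5})
    pairs = sorted(zip(bas.lengths, bas.abundances))
    assert pairs == [(1.0, 0.25), (1.0, 0.25), (1.0, 0.5), (2.0, 0.5)]
    assert bas.T_bar == pytest.approx(2.0)


def test_star_tree_abundances(rng):
    p = random_abundances(rng, n=6)
    labels = [f"S{i}" for i in range(6)]
    nwk = "(" + ",".join(f"{l}:3.0" for l in labels) + ");"
    bas = branch_abundances(parse_newick(nwk), dict(zip(labels, p)))
    assert np.allclose(sorted(bas.abundances), sorted(p))
    assert bas.T_bar == pytest.approx(3.0)


def test_concentrated_abundance_ultrametric(worked_tree):
    bas = branch_abundances(worked_tree, {"A": 1.0})
    assert bas.T_bar == pytest.approx(2.0)


def test_missing_tip_error(worked_tree):
    with pytest.raises(KeyError):
        branch_abundances(worked_tree, {"A": 0.5, "Q": 0.5})


# ---------------------------------------------------------------------------
# phylogenetic Hill numbers

def test_hill_phylo_worked(worked_tree):
    bas = branch_abundances(worked_tree, {"A": 0.25, "B": 0.25, "C": 0.5})
    mean0, total0 = hill_phylo(bas, 0)
    assert total0 == pytest.approx(5.0)       # Faith's PD
    assert mean0 == pytest.approx(2.5)
    mean2, total2 = hill_phylo(bas, 2)
    assert mean2 == pytest.approx(1 / 0.4375, abs=1e-9)
    assert total2 == pytest.approx(2 * (1 / 0.4375), abs=1e-9)


def test_star_tree_reduces_to_taxonomic(rng):
    """On a star tree every tip is its own branch, so mean phylogenetic
    diversity equals the taxonomic Hill number and total PD = depth * qD."""
    for _ in range(10):
        p = random_abundances(rng, n=8)
        labels = [f"S{i}" for i in range(8)]
        T = float(rng.uniform(0.5, 10))
        tree = parse_newick(
            "(" + ",".join(f"{l}:{T!r}" for l in labels) + ");")
        bas = branch_abundances(tree, dict(zip(labels, p)))
        for q in (0.0, 1.0, 2.0):
            mean, total = hill_phylo(bas, q)
            qd = hill_taxonomic(p, q)
            assert mean == pytest.approx(qd, abs=1e-9)
            assert total == pytest.approx(T * qd, abs=1e-8)


def test_faith_oracle_random_trees(rng):
    """q = 0 total PD equals brute-force Faith's PD on random trees."""
    for _ in range(100):
        n = int(rng.integers(4, 50))
        tree = _random_tree(rng, n)
        labels = tip_labels(tree)
        k = int(rng.integers(2, n + 1))
        chosen = list(rng.choice(labels, size=k, replace=False))
        p = dict(zip(chosen, random_abundances(rng, n=k)))
        _, total0 = hill_phylo(branch_abundances(tree, p), 0)
        assert total0 == pytest.approx(_faith_pd_bruteforce(tree, p),
                                       abs=1e-9)


def test_replication_two_disjoint_subtrees(rng):
    """Joining two copies of an ultrametric community at a root with
    zero-length connectors, half the abundance each, doubles the mean
    diversity."""
    p = random_abundances(rng, n=4)
    labels = [f"S{i}" for i in range(4)]
    sub_a = "(" + ",".join(f"A{i}:2.0" for i in range(4)) + ")"
    sub_b = "(" + ",".join(f"B{i}:2.0" for i in range(4)) + ")"
    joined = parse_newick(f"({sub_a}:0.0,{sub_b}:0.0);")
    single = parse_newick(sub_a + ";")
    p_single = dict(zip([f"A{i}" for i in range(4)], p))
    p_joined = {**{f"A{i}": v / 2 for i, v in enumerate(p)},
                **{f"B{i}": v / 2 for i, v in enumerate(p)}}
    for q in (0.0, 1.0, 2.0):
        m1, _ = hill_phylo(branch_abundances(single, p_single), q)
        m2, _ = hill_phylo(branch_abundances(joined, p_joined), q)
        assert m2 == pytest.approx(2 * m1, abs=1e-9)


def test_mean_diversity_monotone_in_q(rng):
    qs = np.linspace(0, 3, 16)
    for _ in range(25):
        tree = _random_tree(rng, int(rng.integers(4, 12)))
        labels = tip_labels(tree)
        p = dict(zip(labels, random_abundances(rng, n=len(labels))))
        bas = branch_abundances(tree, p)
        means = [hill_phylo(bas, q)[0] for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


def test_q1_continuity(worked_tree):
    bas = branch_abundances(worked_tree, {"A": 0.25, "B": 0.25, "C": 0.5})
    m1, t1 = hill_phylo(bas, 1.0)
    for q in (1 - 1e-6, 1 + 1e-6):
        m, t = hill_phylo(bas, q)
        assert abs(m - m1) < 1e-4
        assert abs(t - t1) < 1e-4
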