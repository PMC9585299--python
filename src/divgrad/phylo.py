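"""Phylogenetic Hill numbers from branch abundances.

Every branch segment i of a rooted tree, with length L_i, carries the
summed relative abundance a_i of the tips descending from it.  The
abundance-weighted mean tip depth is T_bar = sum_i L_i a_i (for an
ultrametric tree with every tip present this equals the root-to-tip
depth).  The mean phylogenetic diversity of order q is

    qDbar = [ sum_i (L_i / T_bar) a_i^q ] ** (1 / (1 - q))     (q != 1)
    1Dbar = exp( - sum_i (L_i / T_bar) a_i ln a_i )

i.e. the effective number of equally abundant, maximally distinct lineages;
total phylogenetic diversity is T_bar * qDbar, the effective total branch
length, which at q = 0 reduces exactly to Faith's PD (the summed length of
all branches with positive descendant abundance).

Trees are handled through dendropy; taxa are matched to tips by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .taxonomic import _Q_ONE_WINDOW

__all__ = [
    "read_newick",
    "parse_newick",
    "write_newick",
    "prune_to",
    "branch_abundances",
    "BranchAbundanceSet",
    "hill_phylo",
]


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above node {name!r}")
        if not np.isfinite(node.edge.length) or node.edge.length < 0:
            name = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"invalid branch length on edge above node {name!r}")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree (validated)."""
    if not newick.strip().endswith(";"):
        raise ValueError("newick string must end with ';'")
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True, rooting="force-rooted",
    )
    return _validate_tree(tree)


def read_newick(path) -> dendropy.Tree:
    """Read a rooted newick tree from ``path``; branch lengths required on
    every non-root edge, zero-length branches retained."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Smallest subtree of ``tree`` containing ``taxa``.

    Unbranched internal nodes are collapsed with their edge lengths summed,
    so every retained tip keeps its original root-to-tip depth (the root is
    kept at the original height of the retained subtree).
    """
    wanted = set(taxa)
    have = set(tip_labels(tree))
    missing = sorted(wanted - have)
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")

    def _quote(label: str) -> str:
        if any(c in label for c in " ()[]:;,'"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def _prune(node):
        """Return (newick fragment, edge length) or None if no wanted tips."""
        edge = node.edge.length or 0.0
        if node.is_leaf():
            if node.taxon.label in wanted:
                return _quote(node.taxon.label), edge
            return None
        kept = [r for r in (_prune(c) for c in node.child_nodes()) if r]
        if not kept:
            return None
        if len(kept) == 1:
            # collapse the unbranched node, summing edge lengths
            frag, child_edge = kept[0]
            return frag, child_edge + edge
        inner = ",".join(f"{frag}:{elen!r}" for frag, elen in kept)
        return f"({inner})", edge

    result = _prune(tree.seed_node)
    # root retained at the original root height: a single surviving lineage
    # hangs below the root on its accumulated stem edge
    frag, edge = result
    if frag.startswith("(") and edge == 0.0:
        newick = frag + ";"
    else:
        newick = f"({frag}:{edge!r});"
    return parse_newick(newick)


@dataclass(frozen=True)
class BranchAbundanceSet:
    """Per-branch lengths and aggregated descendant relative abundances.

    Only branches with positive descendant abundance are stored.  ``T_bar``
    is the abundance-weighted mean tip depth sum(L_i * a_i).
    """

    lengths: np.ndarray = field(repr=False)
    abundances: np.ndarray = field(repr=False)

    def __post_init__(self):
        L = np.asarray(self.lengths, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if L.shape != a.shape:
            raise ValueError("lengths and abundances must align")
        if np.any(a <= 0) or np.any(a > 1 + 1e-9):
            raise ValueError("branch abundances must lie in (0, 1]")
        if np.any(L < 0):
            raise ValueError("branch lengths must be >= 0")
        object.__setattr__(self, "lengths", L)
        object.__setattr__(self, "abundances", a)

    @property
    def T_bar(self) -> float:
        return float(np.sum(self.lengths * self.abundances))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"L": self.lengths, "a": self.abundances})


def branch_abundances(
    tree: dendropy.Tree, p: Mapping[str, float]
) -> BranchAbundanceSet:
    """Aggregate tip relative abundances onto branches (single post-order
    traversal).

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree whose tips cover every positive-abundance taxon.
    p : mapping taxon label -> relative abundance
        Zero-abundance tips may be present in the tree; they simply
        contribute nothing.  Abundances are renormalised to sum to 1.
    """
    labels = set(tip_labels(tree))
    pos = {k: v for k, v in p.items() if v > 0}
    missing = sorted(set(pos) - labels)
    if missing:
        raise KeyError(f"taxa with abundance but no tip in tree: {missing}")
    total = sum(pos.values())
    if total <= 0:
        raise ValueError("no positive abundances")
    lengths, abundances = [], []
    acc: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            a = pos.get(node.taxon.label, 0.0) / total
        else:
            a = sum(acc.pop(id(c)) for c in node.child_nodes())
        acc[id(node)] = a
        if node.parent_node is not None and a > 0:
            lengths.append(node.edge.length)
            abundances.append(a)
    return BranchAbundanceSet(np.array(lengths), np.array(abundances))


def hill_phylo(bas: BranchAbundanceSet, q: float) -> tuple[float, float]:
    """Phylogenetic Hill number of order q from branch abundances.

    Returns
    -------
    (mean_diversity, total_PD)
        ``mean_diversity`` is the effective number of maximally distinct
        lineages qDbar; ``total_PD`` = T_bar * qDbar is the effective total
        branch length — the quantity reported as "phylogenetic entities"
        (at q = 0 it equals Faith's PD).
    """
    if q < 0:
        raise ValueError(f"diversity order q must be >= 0, got {q}")
    L = bas.lengths
    a = bas.abundances
    T = bas.T_bar
    if T <= 0:
        raise ValueError("tree has zero abundance-weighted depth")
    w = L / T
    if abs(q - 1.0) < _Q_ONE_WINDOW:
        mean = float(np.exp(-np.sum(w * a * np.log(a))))
    else:
        s = float(np.sum(w * a ** q))
        mean = s ** (1.0 / (1.0 - q))
    return mean, T * mean
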