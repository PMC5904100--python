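"""Internode certainty, tree certainty and shared-clade congruence.

IC follows the two-most-prevalent-bipartition normalisation: for a focal
internal branch with relative frequency f1 across the candidate tree set and
strongest conflicting bipartition frequency f2, with p_i = f_i/(f1+f2),

    IC = 1 + p1*log2(p1) + p2*log2(p2),

negated when the conflict is more frequent than the branch itself.  Tree
certainty TC is the sum of IC over the internal branches of a tree, and the
candidate with the highest TC is the most self-congruent tree of the set.
Frequencies count trees (not bootstrap replicates), and bipartitions of
multifurcating candidates contribute each resolved branch once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
    )


def _bipartitions(tree: dendropy.Tree, leaf_order: list[str]) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf subsets (side without leaf_order[0])."""
    all_leaves = frozenset(leaf_order)
    ref = leaf_order[0]
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def _conflicts(a: frozenset[str], b: frozenset[str], all_leaves: frozenset[str]) -> bool:
    """Two bipartitions conflict iff they are incompatible on the shared leaf set."""
    if a == b:
        return False
    ac, bc = all_leaves - a, all_leaves - b
    return all((a & b, a & bc, ac & b, ac & bc))


@dataclass(frozen=True)
class BranchCertainty:
    bipartition: frozenset[str]
    f1: float
    f2: float
    conflict: frozenset[str] | None
    ic: float


@dataclass
class BipartitionProfile:
    branches: list[BranchCertainty]

    @property
    def tree_certainty(self) -> float:
        return sum(b.ic for b in self.branches)


def _check_leaf_sets(newicks: list[str]) -> list[str]:
    leaf_sets = []
    for nwk in newicks:
        t = _parse(nwk)
        leaf_sets.append(sorted(lf.taxon.label for lf in t.leaf_node_iter()))
    ref = set(leaf_sets[0])
    for ls in leaf_sets[1:]:
        if set(ls) != ref:
            diff = sorted(ref ^ set(ls))
            raise ValueError(f"trees do not share a leaf set; symmetric difference: {diff}")
    return leaf_sets[0]


def internode_certainty(focal_newick: str, tree_set: list[str]) -> BipartitionProfile:
    """IC for every internal branch of the focal tree across ``tree_set``."""
    leaf_order = _check_leaf_sets([focal_newick] + list(tree_set))
    all_leaves = frozenset(leaf_order)
    n_trees = len(tree_set)
    freq: dict[frozenset[str], int] = {}
    for nwk in tree_set:
        for bp in _bipartitions(_parse(nwk), leaf_order):
            freq[bp] = freq.get(bp, 0) + 1

    branches = []
    for bp in sorted(_bipartitions(_parse(focal_newick), leaf_order), key=lambda s: sorted(s)):
        f1 = freq.get(bp, 0) / n_trees
        best_conflict, f2 = None, 0.0
        for other, cnt in freq.items():
            if _conflicts(bp, other, all_leaves) and cnt / n_trees > f2:
                best_conflict, f2 = other, cnt / n_trees
        if f2 == 0.0:
            ic = 1.0
        else:
            p1, p2 = f1 / (f1 + f2), f2 / (f1 + f2)
            ic = 1.0 + p1 * math.log2(p1) + p2 * math.log2(p2)
            if f2 > f1:
                ic = -ic
        branches.append(BranchCertainty(bp, f1, f2, best_conflict, ic))
    return BipartitionProfile(branches)


def select_best_tree(tree_set: list[str]) -> tuple[str, list[tuple[int, float]], bool]:
    """Tree with the highest TC; ties pick the lexicographically smallest serialization.

    Returns (best newick, [(index, TC)] table, tie flag).
    """
    if len(tree_set) < 2:
        raise ValueError("need at least 2 trees")
    _check_leaf_sets(list(tree_set))
    table = [(i, internode_certainty(nwk, tree_set).tree_certainty) for i, nwk in enumerate(tree_set)]
    best_tc = max(tc for _, tc in table)
    winners = [i for i, tc in table if math.isclose(tc, best_tc, abs_tol=1e-12)]
    tie = len(winners) > 1
    best = min((tree_set[i] for i in winners)) if tie else tree_set[winners[0]]
    return best, table, tie


def shared_clade_congruence(
    tree_newick: str, reference_newick: str, link_map: dict[str, str]
) -> list[tuple[frozenset[str], str]]:
    """Classify each reference clade as congruent / compatible / conflicting.

    ``link_map`` maps tree leaves -> reference leaves (a subset).  A clade is
    congruent when its linked members are monophyletic in the tree, compatible
    when they form a clade once unlinked tree leaves are ignored, and
    conflicting otherwise.
    """
    if not link_map:
        raise ValueError("empty link map")
    tree = _parse(tree_newick)
    ref = _parse(reference_newick)
    inverse: dict[str, set[str]] = {}
    for t_leaf, r_leaf in link_map.items():
        inverse.setdefault(r_leaf, set()).add(t_leaf)

    tree_clades = {
        frozenset(lf.taxon.label for lf in n.leaf_iter()) for n in tree.preorder_internal_node_iter()
    }
    linked_leaves = set(link_map)
    restricted_clades = {frozenset(c & linked_leaves) for c in tree_clades}

    out = []
    for node in ref.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        r_clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        linked = frozenset().union(*(inverse.get(r, set()) for r in r_clade))
        if len(linked) < 2:
            continue
        if linked in tree_clades:
            verdict = "congruent"
        elif linked in restricted_clades:
            verdict = "compatible"
        else:
            verdict = "conflicting"
        out.append((r_clade, verdict))
    return out
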