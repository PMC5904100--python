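"""Support-threshold clade taxonomy over dual-support trees.

Internal branches carry two support values (ultrafast bootstrap %, SH-aLRT %);
a branch is trusted only when UFBoot >= 95 AND SH-aLRT >= 85 (both boundaries
inclusive), and every untrusted branch is contracted before any rank is named.
Rank assignment then walks each seeded order-level clade: maximal supported
subclades with at least three leaves are rank-eligible, two-leaf subclades
become "<parent>-IS" (incertae sedis), and a new rank level opens only when at
least two eligible subclades need distinguishing.  Sibling labels (Greek
letters at the first level, integers below) are handed out in descending
stem-branch-length order, the deterministic completion of "start from the
clade with the longest branch".
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

GREEK = "αβγδεζηθικλμνξοπρστυφχψω"

MIN_UFBOOT = 95.0
MIN_SHALRT = 85.0
MIN_CLADE = 3

_SUPPORT_RE = re.compile(r"^(?:(?P<name>.*)\|)?(?P<uf>[0-9.]+)/(?P<sha>[0-9.]+)$")


class SupportTree:
    """Rooted tree whose internal nodes carry (ufboot, shalrt) support pairs.

    Wraps a dendropy tree; supports live in ``node.ufboot``/``node.shalrt``
    and serialize as internal-node labels ``[name|]ufboot/shalrt``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
        )
        tree.is_rooted = True
        for node in tree.preorder_node_iter():
            node.ufboot = None
            node.shalrt = None
            node.clade_name = None
            if node.is_leaf() or node.label is None:
                continue
            m = _SUPPORT_RE.match(node.label)
            if m:
                node.ufboot = float(m.group("uf"))
                node.shalrt = float(m.group("sha"))
                node.clade_name = m.group("name") or None
        return cls(tree)

    def to_newick(self) -> str:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            uf, sha = getattr(node, "ufboot", None), getattr(node, "shalrt", None)
            if uf is not None:
                name = getattr(node, "clade_name", None)
                sup = f"{uf:g}/{sha:g}"
                node.label = f"{name}|{sup}" if name else sup
        out = io.StringIO()
        self.tree.write(file=out, schema="newick", suppress_rooting=True, unquoted_underscores=True)
        return out.getvalue().strip()

    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "SupportTree":
        return SupportTree.from_newick(self.to_newick())


def collapse_unsupported(
    tree: SupportTree, min_ufboot: float = MIN_UFBOOT, min_shalrt: float = MIN_SHALRT
) -> SupportTree:
    """Contract every internal branch failing either support threshold.

    Children of a collapsed node re-attach to its parent; surviving branches
    keep their lengths and supports; leaves are never removed.  Both
    thresholds are inclusive (a 95/85 branch survives).
    """
    out = tree.clone()
    to_collapse = []
    for node in out.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        uf, sha = getattr(node, "ufboot", None), getattr(node, "shalrt", None)
        if uf is None or sha is None:
            leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
            raise ValueError(f"missing support on internal branch above leaves {leaves[:3]}...")
        if uf < min_ufboot or sha < min_shalrt:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


@dataclass(frozen=True)
class RankedTaxon:
    name: str
    parent: str | None
    level: int  # 0 = order prefix, 1 = Greek, >= 2 numeric
    members: frozenset[str]
    is_incertae_sedis: bool = False
    is_terminal: bool = False
    stem_length: float = 0.0


@dataclass
class LineageSeed:
    """Anchors order prefixes to leaves present in the tree.

    ``anchors`` maps leaf id -> order prefix (e.g. NP).  The order-level clade
    for a prefix is the MRCA of all its anchor leaves; leaves outside every
    seeded order fall into a reserved bucket named ``unplaced_name``.
    """

    anchors: dict[str, str]
    unplaced_name: str = "IS"

    def prefixes(self) -> list[str]:
        seen: list[str] = []
        for p in self.anchors.values():
            if p not in seen:
                seen.append(p)
        return seen


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _child_sort_key(node):
    leaves = sorted(_leafset(node))
    return (-(node.edge.length or 0.0), -len(leaves), leaves[0])


def _greek_label(i: int) -> str:
    # cycle with a numeric suffix if ever more than 24 siblings need labels
    return GREEK[i % len(GREEK)] + ("" if i < len(GREEK) else str(i // len(GREEK) + 1))


def assign_ranks(
    tree: SupportTree,
    seeds: LineageSeed,
    min_clade: int = MIN_CLADE,
    manual_overrides: list[frozenset[str]] | None = None,
) -> list[RankedTaxon]:
    """Name the multilevel taxonomy of a collapsed support tree.

    ``manual_overrides`` are leaf sets that must receive their own rank even
    when the at-least-two-eligible-siblings rule would leave the parent
    terminal (the escape hatch for conspicuously long-branched subclades).
    """
    overrides = [frozenset(o) for o in (manual_overrides or [])]
    all_clades = {_leafset(n) for n in tree.tree.preorder_node_iter() if not n.is_leaf()}
    for ov in overrides:
        if ov not in all_clades:
            raise ValueError(f"override clade not monophyletic in collapsed tree: {sorted(ov)[:3]}...")

    taxa: list[RankedTaxon] = []
    tree_leaves = set(tree.leaf_ids())
    for anchor in seeds.anchors:
        if anchor not in tree_leaves:
            raise ValueError(f"seed anchor {anchor!r} absent from tree")

    # locate order clades as MRCAs of anchor leaves
    order_nodes: dict[str, object] = {}
    for prefix in seeds.prefixes():
        anchor_leaves = [a for a, p in seeds.anchors.items() if p == prefix]
        mrca = tree.tree.mrca(taxon_labels=anchor_leaves)
        order_nodes[prefix] = mrca
    order_sets = {p: _leafset(n) for p, n in order_nodes.items()}
    for p1 in order_sets:
        for p2 in order_sets:
            if p1 < p2 and order_sets[p1] & order_sets[p2]:
                raise ValueError(f"seeded order clades {p1} and {p2} overlap")

    unplaced = tree_leaves - set().union(*order_sets.values())
    if unplaced:
        taxa.append(
            RankedTaxon(seeds.unplaced_name, None, 0, frozenset(unplaced), is_incertae_sedis=True, is_terminal=True)
        )

    def recurse(node, name: str, level: int) -> None:
        children = sorted((c for c in node.child_nodes()), key=_child_sort_key)
        eligible = [c for c in children if not c.is_leaf() and len(_leafset(c)) >= min_clade]
        forced = [c for c in eligible if _leafset(c) in overrides]
        open_rank = len(eligible) >= 2 or bool(forced)
        named_children = eligible if len(eligible) >= 2 else forced

        is_cnt = 0
        for c in children:
            ls = _leafset(c)
            if not c.is_leaf() and len(ls) == 2:
                is_cnt += 1
                suffix = "-IS" if is_cnt == 1 else f"-IS{is_cnt}"
                taxa.append(
                    RankedTaxon(name + suffix, name, level + 1, ls, is_incertae_sedis=True, is_terminal=True,
                                stem_length=c.edge.length or 0.0)
                )

        if not open_rank:
            return
        label_i = 0
        for c in eligible:
            if c not in named_children:
                continue
            if level == 0:
                label = _greek_label(label_i)
                child_name = f"{name}-{label}"
            else:
                label = str(label_i + 1)
                child_name = f"{name}-{label}" if level == 1 else f"{name}.{label}"
            label_i += 1
            sub = RankedTaxon(child_name, name, level + 1, _leafset(c), stem_length=c.edge.length or 0.0)
            taxa.append(sub)
            recurse(c, child_name, level + 1)

    for prefix in seeds.prefixes():
        node = order_nodes[prefix]
        taxa.append(
            RankedTaxon(prefix, None, 0, order_sets[prefix], stem_length=node.edge.length or 0.0)
        )
        recurse(node, prefix, 0)

    # mark terminal taxa: those with no named child
    parents = {t.parent for t in taxa if t.parent}
    names = {t.name for t in taxa}
    final = []
    for t in taxa:
        has_child = any(
            (o.parent == t.name and not o.is_incertae_sedis) for o in taxa
        )
        final.append(
            RankedTaxon(t.name, t.parent, t.level, t.members, t.is_incertae_sedis, not has_child, t.stem_length)
        )
    assert len(names) == len(taxa), "duplicate taxon names"
    return final


def leaf_lineages(taxa: list[RankedTaxon]) -> dict[str, str]:
    """Most specific taxon name per leaf."""
    out: dict[str, str] = {}
    for t in sorted(taxa, key=lambda t: t.level):
        for leaf in t.members:
            out[leaf] = t.name
    return out


def classify(
    query_identity: dict[str, float],
    taxa: list[RankedTaxon],
    otu_of_rep: dict[str, str] | None = None,
    min_identity: float = 0.96,
    lca_radius: float = 0.90,
) -> str:
    """Classify a query from its identities to OTU representatives.

    ``query_identity`` maps representative leaf id -> identity with the query.
    Nearest representative at >= min_identity wins its most specific taxon;
    otherwise the deepest taxon covering every representative within
    ``lca_radius``; otherwise "unclassified".
    """
    if not taxa:
        raise ValueError("empty taxonomy")
    lineage = leaf_lineages(taxa)
    best_rep = max(sorted(query_identity), key=lambda r: query_identity[r])
    if query_identity[best_rep] >= min_identity:
        return lineage.get(best_rep, "unclassified")
    near = {r for r, ident in query_identity.items() if ident >= lca_radius}
    if near:
        covering = [t for t in taxa if near <= t.members]
        if covering:
            return max(covering, key=lambda t: t.level).name
    return "unclassified"


def export_taxonomy(taxa: list[RankedTaxon], tree: SupportTree) -> tuple[str, str]:
    """(annotated Newick, lineage TSV) for a built taxonomy.

    Internal nodes matching a named clade get labels ``name|ufboot/shalrt``;
    the TSV maps each leaf to its full lineage path (names are hierarchical so
    the most specific name encodes the whole lineage).
    """
    by_members = {t.members: t.name for t in taxa}
    out = tree.clone()
    for node in out.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        name = by_members.get(_leafset(node))
        node.clade_name = name
    newick = out.to_newick()
    lineage = leaf_lineages(taxa)
    lines = ["seqid\tlineage"]
    for leaf in sorted(lineage):
        lines.append(f"{leaf}\t{lineage[leaf]}")
    return newick, "\n".join(lines) + "\n"


def import_taxonomy(lineage_tsv: str) -> dict[str, str]:
    out = {}
    for line in lineage_tsv.strip().splitlines()[1:]:
        seqid, name = line.split("\t")
        out[seqid] = name
    return out


def rogue_report(tree: SupportTree) -> list[tuple[str, float, float]]:
    """Leaf-stability proxy: (leaf, attachment-edge support, isolation score).

    Isolation = terminal branch length divided by the mean terminal branch
    length; low attachment support plus high isolation flags rogue candidates.
    The report aids manual judgement only; nothing is removed automatically.
    """
    leaves = list(tree.tree.leaf_node_iter())
    lengths = [lf.edge.length or 0.0 for lf in leaves]
    mean_len = sum(lengths) / len(lengths) if lengths else 0.0
    rows = []
    for lf, ln in zip(leaves, lengths):
        parent = lf.parent_node
        support = getattr(parent, "ufboot", None) if parent is not None else None
        iso = ln / mean_len if mean_len > 0 else 0.0
        rows.append((lf.taxon.label, support if support is not None else float("nan"), iso))
    return rows
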