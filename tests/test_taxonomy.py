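"""Dual-support collapsing and deterministic multilevel rank assignment."""

import pytest

from amoatax.taxonomy import (
    LineageSeed,
    SupportTree,
    assign_ranks,
    classify,
    collapse_unsupported,
    export_taxonomy,
    import_taxonomy,
    leaf_lineages,
)


def _clades(tree):
    return {
        frozenset(lf.taxon.label for lf in n.leaf_iter())
        for n in tree.tree.preorder_node_iter()
        if not n.is_leaf()
    }


BOUNDARY_NEWICK = (
    "(((A:1,B:1)'95/85':1,(C:1,D:1)'94/90':1)'100/100':1,(E:1,F:1)'100/84.9':1)root;"
)


class TestCollapse:
    def test_boundary_branches(self):
        tree = SupportTree.from_newick(BOUNDARY_NEWICK)
        collapsed = collapse_unsupported(tree)
        clades = _clades(collapsed)
        assert frozenset("AB") in clades  # 95/85 retained: thresholds inclusive
        assert frozenset("CD") not in clades  # ufboot 94 -> collapsed
        assert frozenset("EF") not in clades  # sh-alrt 84.9 -> collapsed
        assert frozenset("ABCD") in clades  # fully supported branch kept

    def test_fully_supported_tree_unchanged(self):
        nwk = "(((A:1,B:1)'99/99':1,C:1)'97/91':1,(D:1,E:1)'100/100':1)root;"
        tree = SupportTree.from_newick(nwk)
        assert _clades(collapse_unsupported(tree)) == _clades(tree)

    def test_idempotent(self):
        tree = SupportTree.from_newick(BOUNDARY_NEWICK)
        once = collapse_unsupported(tree)
        twice = collapse_unsupported(once)
        assert _clades(once) == _clades(twice)

    def test_missing_support_is_an_error(self):
        tree = SupportTree.from_newick("(((A:1,B:1):1,C:1)'99/99':1,(D:1,E:1)'99/99':1)root;")
        with pytest.raises(ValueError, match="missing support"):
            collapse_unsupported(tree)

    def test_leaves_never_removed(self):
        tree = SupportTree.from_newick(BOUNDARY_NEWICK)
        assert sorted(collapse_unsupported(tree).leaf_ids()) == sorted(tree.leaf_ids())

    def test_threshold_monotonicity(self, default_dataset):
        """Raising either support threshold never retains extra clades.

        (Named-taxon counts are not monotone: losing a lone eligible child
        can splice its subclades into the parent and open a new rank, so the
        monotone quantity is the retained clade set, not the name count.)
        """
        tree = default_dataset.tree
        clade_sets = []
        for uf, sha in [(60, 50), (85, 75), (95, 85)]:
            clade_sets.append(_clades(collapse_unsupported(tree, uf, sha)))
        assert clade_sets[2] <= clade_sets[1] <= clade_sets[0]


# order NP: children of sizes [5, 4, 1] with stem lengths [0.02, 0.07, -];
# second order NS is a trivial 2-leaf order
RANK_NEWICK = (
    "(((x1:1,x2:1,x3:1,x4:1,x5:1)'100/100':0.02,"
    "(y1:1,y2:1,y3:1,y4:1)'100/100':0.07,z:1)'100/100':0.5,"
    "(a1:1,a2:1)'100/100':0.3)root;"
)


class TestAssignRanks:
    def _taxa(self, **kw):
        tree = SupportTree.from_newick(RANK_NEWICK)
        seeds = LineageSeed({"x1": "NP", "y1": "NP", "a1": "NS", "a2": "NS"})
        return {t.name: t for t in assign_ranks(tree, seeds, **kw)}

    def test_greek_labels_follow_stem_length_order(self):
        taxa = self._taxa()
        # longest stem (0.07, the 4-leaf clade) takes the first Greek letter
        assert taxa["NP-α"].members == frozenset({"y1", "y2", "y3", "y4"})
        assert taxa["NP-β"].members == frozenset({"x1", "x2", "x3", "x4", "x5"})
        # the singleton z stays directly in the order
        assert leaf_lineages(list(taxa.values()))["z"] == "NP"

    def test_trivial_order_is_terminal(self):
        taxa = self._taxa()
        assert taxa["NS"].is_terminal
        assert taxa["NS"].members == frozenset({"a1", "a2"})

    def test_single_eligible_child_opens_no_rank(self):
        nwk = (
            "(((x1:1,x2:1,x3:1,x4:1)'100/100':0.1,z:1)'100/100':0.5,"
            "(a1:1,a2:1)'100/100':0.3)root;"
        )
        seeds = LineageSeed({"x1": "NP", "z": "NP", "a1": "NS", "a2": "NS"})
        taxa = {t.name: t for t in assign_ranks(SupportTree.from_newick(nwk), seeds)}
        assert "NP-α" not in taxa
        assert taxa["NP"].is_terminal

    def test_two_leaf_child_becomes_incertae_sedis(self):
        nwk = (
            "(((x1:1,x2:1,x3:1)'100/100':0.1,(w1:1,w2:1)'100/100':0.2,"
            "(y1:1,y2:1,y3:1)'100/100':0.15)'100/100':0.5,(a1:1,a2:1)'100/100':0.3)root;"
        )
        seeds = LineageSeed({"x1": "NP", "y1": "NP", "a1": "NS", "a2": "NS"})
        taxa = {t.name: t for t in assign_ranks(SupportTree.from_newick(nwk), seeds)}
        assert taxa["NP-IS"].members == frozenset({"w1", "w2"})
        assert taxa["NP-IS"].is_incertae_sedis

    def test_manual_override_forces_rank(self):
        nwk = (
            "(((x1:1,x2:1,x3:1,x4:1)'100/100':0.9,z:1,w:1)'100/100':0.5,"
            "(a1:1,a2:1)'100/100':0.3)root;"
        )
        seeds = LineageSeed({"x1": "NP", "z": "NP", "a1": "NS", "a2": "NS"})
        taxa = {t.name: t for t in assign_ranks(
            SupportTree.from_newick(nwk), seeds,
            manual_overrides=[frozenset({"x1", "x2", "x3", "x4"})],
        )}
        assert "NP-α" in taxa  # forced despite a single eligible child
        assert taxa["NP-α"].members == frozenset({"x1", "x2", "x3", "x4"})

    def test_override_must_be_monophyletic(self):
        tree = SupportTree.from_newick(RANK_NEWICK)
        seeds = LineageSeed({"x1": "NP", "y1": "NP", "a1": "NS", "a2": "NS"})
        with pytest.raises(ValueError, match="monophyletic"):
            assign_ranks(tree, seeds, manual_overrides=[frozenset({"x1", "y1"})])

    def test_missing_anchor_is_an_error(self):
        tree = SupportTree.from_newick(RANK_NEWICK)
        with pytest.raises(ValueError, match="absent"):
            assign_ranks(tree, LineageSeed({"nope": "NP"}))

    def test_nesting_and_determinism(self, default_dataset):
        gt = default_dataset.ground_truth
        taxa = assign_ranks(collapse_unsupported(default_dataset.tree), gt.seeds)
        by_name = {t.name: t for t in taxa}
        for t in taxa:
            if t.parent:
                assert t.members < by_name[t.parent].members  # strict nesting
        again = assign_ranks(collapse_unsupported(default_dataset.tree), gt.seeds)
        assert [(t.name, t.members) for t in again] == [(t.name, t.members) for t in taxa]


class TestClassify:
    def _setup(self):
        taxa = list(self._taxa().values())
        return taxa

    def _taxa(self):
        tree = SupportTree.from_newick(RANK_NEWICK)
        seeds = LineageSeed({"x1": "NP", "y1": "NP", "a1": "NS", "a2": "NS"})
        return {t.name: t for t in assign_ranks(tree, seeds)}

    def test_exact_match_gets_most_specific_taxon(self):
        taxa = self._setup()
        idents = {lf: 0.5 for t in taxa for lf in t.members}
        idents["y1"] = 1.0
        assert classify(idents, taxa) == "NP-α"

    def test_spread_matches_fall_back_to_lca(self):
        taxa = self._setup()
        idents = {lf: 0.5 for t in taxa for lf in t.members}
        idents["y1"] = 0.92
        idents["x1"] = 0.91
        assert classify(idents, taxa) == "NP"

    def test_distant_query_unclassified(self):
        taxa = self._setup()
        idents = {lf: 0.6 for t in taxa for lf in t.members}
        assert classify(idents, taxa) == "unclassified"

    def test_empty_taxonomy_raises(self):
        with pytest.raises(ValueError):
            classify({"x": 1.0}, [])


class TestExport:
    def test_lineage_roundtrip(self, default_dataset):
        gt = default_dataset.ground_truth
        collapsed = collapse_unsupported(default_dataset.tree)
        taxa = assign_ranks(collapsed, gt.seeds)
        newick, lineage_tsv = export_taxonomy(taxa, collapsed)
        assert import_taxonomy(lineage_tsv) == leaf_lineages(taxa)
        # annotated tree re-parses with named internal clades intact
        reread = SupportTree.from_newick(newick)
        names = {
            n.clade_name
            for n in reread.tree.preorder_node_iter()
            if getattr(n, "clade_name", None)
        }
        assert {t.name for t in taxa if not t.is_incertae_sedis} <= names | {None}

    def test_is_suffix_serialized(self):
        nwk = (
            "(((x1:1,x2:1,x3:1)'100/100':0.1,(w1:1,w2:1)'100/100':0.2,"
            "(y1:1,y2:1,y3:1)'100/100':0.15)'100/100':0.5,(a1:1,a2:1)'100/100':0.3)root;"
        )
        seeds = LineageSeed({"x1": "NP", "y1": "NP", "a1": "NS", "a2": "NS"})
        taxa = assign_ranks(SupportTree.from_newick(nwk), seeds)
        _, lineage_tsv = export_taxonomy(taxa, SupportTree.from_newick(nwk))
        assert "NP-IS" in lineage_tsv

    def test_deep_rank_grammar(self):
        """A level-4 name carries dotted numerals after the Greek letter."""
        nwk = (
            "((((((l1:1,l2:1,l3:1)'100/100':0.3,(l4:1,l5:1,l6:1)'100/100':0.2)'100/100':0.3,"
            "(m1:1,m2:1,m3:1)'100/100':0.1)'100/100':0.4,"
            "(n1:1,n2:1,n3:1)'100/100':0.2)'100/100':0.5,"
            "(p1:1,p2:1,p3:1)'100/100':0.2,q:1)'100/100':0.6,(a1:1,a2:1)'100/100':0.3)root;"
        )
        seeds = LineageSeed({"l1": "NP", "p1": "NP", "a1": "NS", "a2": "NS"})
        names = {t.name for t in assign_ranks(SupportTree.from_newick(nwk), seeds)}
        assert "NP-α-1.1" in names or "NP-α-1.2" in names
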