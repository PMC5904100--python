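"""Generator contracts: determinism, ground-truth registries, clade structure."""

import numpy as np
import pytest
from scipy import stats

from amoatax.records import STOP_CODONS, revcomp
from amoatax.signatures import base_composition, effective_number_of_codons, SYNONYMOUS_FAMILIES
from amoatax.simulate import (
    CorruptionSpec,
    SimConfig,
    clade_codon_weights,
    corrupt_sequences,
    default_clade_distribution,
    default_habitat_tree,
    evolve_sequences,
    make_chimeras,
    make_metadata,
    simulate_dataset,
    simulate_tree,
)
from amoatax.records import AlignedGene


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(seed=0, n_clades=1)
    with pytest.raises(ValueError):
        SimConfig(seed=0, chimera_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(seed=0, per_clade_gc_target=(0.4,))  # wrong arity


def test_config_json_roundtrip():
    cfg = SimConfig(seed=3, n_clades=3, chimera_fraction=0.05)
    assert SimConfig.from_json(cfg.to_json()) == cfg


def test_forced_supports_give_maximal_clades():
    cfg = SimConfig(seed=2, n_clades=4, otus_per_clade=5, unsupported_fraction=0.0)
    tree, gt = simulate_tree(cfg)
    # with every branch supported, each order is a maximal supported clade of 5
    orders = [t for t in gt.true_taxa if t.level == 0]
    assert len(orders) == 4
    assert all(len(t.members) == 5 for t in orders)


def test_seed_fixes_everything():
    cfg = SimConfig(seed=11, n_clades=2, otus_per_clade=4, seqs_per_otu=6)
    ds1, ds2 = simulate_dataset(cfg), simulate_dataset(cfg)
    assert ds1.tree.to_newick() == ds2.tree.to_newick()
    assert [(r.id, r.seq) for r in ds1.raw_records] == [(r.id, r.seq) for r in ds2.raw_records]
    assert ds1.ground_truth.chimera_registry == ds2.ground_truth.chimera_registry
    assert ds1.metadata_rows == ds2.metadata_rows


def test_zero_mutation_rate_keeps_leaves_identical():
    cfg = SimConfig(seed=4, n_clades=2, otus_per_clade=3, mutation_rate=0.0)
    tree, gt = simulate_tree(cfg)
    genes = evolve_sequences(tree, cfg, gt)
    by_clade = {}
    for g in genes:
        by_clade.setdefault(gt.clade_of_leaf[g.id], set()).add(g.coding_seq)
    assert all(len(s) == 1 for s in by_clade.values())


def test_clean_sequences_in_frame_and_stop_free(default_dataset):
    for g in default_dataset.clean_pool:
        assert len(g.coding_seq) == 591
        codons = {g.coding_seq[i : i + 3] for i in range(0, 591, 3)}
        assert not codons & STOP_CODONS


def test_gc_ordering_two_clades():
    cfg = SimConfig(seed=6, n_clades=2, otus_per_clade=5, per_clade_gc_target=(0.40, 0.58))
    tree, gt = simulate_tree(cfg)
    genes = evolve_sequences(tree, cfg, gt)
    gc = {ci: [base_composition(g)[0] for g in genes if gt.clade_of_leaf[g.id] == ci] for ci in (0, 1)}
    assert np.mean(gc[0]) < np.mean(gc[1])


def test_gc_means_monotone_in_target(default_dataset):
    gt = default_dataset.ground_truth
    cfg = default_dataset.config
    means = []
    for ci in range(cfg.n_clades):
        vals = [base_composition(g)[0] for g in default_dataset.otu_representatives
                if gt.clade_of_leaf[g.id] == ci]
        means.append(np.mean(vals))
    assert means == sorted(means)


def test_concentrated_codon_weights_give_nc_20():
    cfg = SimConfig(seed=8, n_clades=2, otus_per_clade=3, mutation_rate=0.0,
                    per_clade_gc_target=(0.5, 0.5))
    tree, gt = simulate_tree(cfg)
    genes = evolve_sequences(tree, cfg, gt)
    # overwrite the clade weights with fully concentrated ones by redrawing
    # the gene from a single-codon-per-family alphabet
    one_codon = {aa: fam[0] for aa, fam in SYNONYMOUS_FAMILIES.items()}
    seq = "".join(one_codon[aa] * 10 for aa in SYNONYMOUS_FAMILIES)
    assert effective_number_of_codons(seq) == 20.0


class TestChimeras:
    def test_zero_fraction_empty_registry(self, default_dataset):
        chims, registry = make_chimeras(default_dataset.clean_pool[:10], 0.0, 0.05, seed=1)
        assert chims == [] and registry == []

    def test_registry_reconstructs_chimeras(self, default_dataset):
        pool = {g.id: g for g in default_dataset.clean_pool}
        for cid, a, b, bp in default_dataset.ground_truth.chimera_registry:
            chim = next(c for c in default_dataset.chimeras if c.id == cid)
            assert chim.coding_seq == pool[a].coding_seq[:bp] + pool[b].coding_seq[bp:]
            assert 0 < bp < 591

    def test_breakpoints_in_central_window(self, default_dataset):
        for _, _, _, bp in default_dataset.ground_truth.chimera_registry:
            assert 0.2 * 591 <= bp <= 0.8 * 591

    def test_identical_pool_raises(self):
        pool = [AlignedGene(f"g{i}", "ACG" * 197) for i in range(5)]
        with pytest.raises(ValueError, match="eligible"):
            make_chimeras(pool, 0.5, 0.05, seed=1)

    def test_midpoint_splice_by_construction(self):
        a = AlignedGene("a", "AAA" * 100)
        b = AlignedGene("b", "AAA" * 50 + "CCC" * 50)
        chims, reg = make_chimeras([a, b], 0.5, 0.05, seed=2, max_parent_divergence=0.6)
        cid, pa, pb, bp = reg[0]
        parents = {"a": a, "b": b}
        chim = chims[0].coding_seq
        assert chim[:bp] == parents[pa].coding_seq[:bp]
        assert chim[bp:] == parents[pb].coding_seq[bp:]


class TestCorruption:
    def test_zero_rates_identity_up_to_strand(self, default_dataset):
        pool = default_dataset.clean_pool[:20]
        spec = CorruptionSpec(0, 0, 0, 0, revcomp_fraction=0.5)
        records, registry, revcomped = corrupt_sequences(pool, spec, seed=3)
        assert all(k == "clean" for k in registry.values())
        by_id = {g.id: g.coding_seq for g in pool}
        for rec in records:
            expect = by_id[rec.id]
            assert rec.seq == (revcomp(expect) if rec.id in revcomped else expect)

    def test_truncations_below_582(self, default_dataset):
        registry = default_dataset.ground_truth.corruption_registry
        raw = {r.id: r.seq for r in default_dataset.raw_records}
        shorts = [i for i, k in registry.items() if k == "short"]
        assert shorts and all(len(raw[i]) < 582 for i in shorts)

    def test_stop_corruptions_have_internal_stop(self, default_dataset):
        registry = default_dataset.ground_truth.corruption_registry
        raw = {r.id: r.seq for r in default_dataset.raw_records}
        revcomped = default_dataset.ground_truth.revcomped
        stopped = [i for i, k in registry.items() if k == "stop"]
        assert stopped
        for i in stopped:
            seq = revcomp(raw[i]) if i in revcomped else raw[i]
            codons = {seq[j : j + 3] for j in range(0, len(seq) - 2, 3)}
            assert codons & STOP_CODONS

    def test_every_sequence_in_exactly_one_registry(self, default_dataset):
        gt = default_dataset.ground_truth
        raw_ids = {r.id for r in default_dataset.raw_records}
        assert set(gt.corruption_registry) == raw_ids
        chim_ids = {c for c, _, _, _ in gt.chimera_registry}
        assert all(gt.corruption_registry[c] == "chimera" for c in chim_ids)


class TestMetadata:
    def test_single_category_all_assigned(self):
        genes = [AlignedGene(f"cl0_otu000_m{i}", "ACG" * 197) for i in range(5)]
        tree = default_habitat_tree()
        rows, habitat_of = make_metadata(
            genes, tree, {0: {"marine/sediment": 1.0}}, seed=1, broader_only_fraction=0.0
        )
        assert all(p == "marine/sediment" for _, p in rows)

    def test_malformed_distribution_rejected(self):
        genes = [AlignedGene("cl0_x", "ACG")]
        with pytest.raises(ValueError, match="sums to"):
            make_metadata(genes, default_habitat_tree(), {0: {"marine/sediment": 0.7}}, seed=1,
                          clade_of_seq={"cl0_x": 0})

    def test_broader_only_fraction_realized(self):
        genes = [AlignedGene(f"cl0_g{i}", "ACG") for i in range(1000)]
        clade_of = {g.id: 0 for g in genes}
        rows, _ = make_metadata(
            genes, default_habitat_tree(), {0: {"marine/water/epipelagic": 1.0}},
            seed=2, broader_only_fraction=0.2, clade_of_seq=clade_of,
        )
        frac = np.mean([p == "marine/water" for _, p in rows])
        lo, hi = stats.binom.interval(0.999, 1000, 0.2)
        assert lo / 1000 <= frac <= hi / 1000

    def test_distribution_recovered_within_binomial_ci(self):
        """{soil 0.8, freshwater 0.2} over 1000 draws lands in the 99% CI."""
        genes = [AlignedGene(f"cl0_g{i}", "ACG") for i in range(1000)]
        clade_of = {g.id: 0 for g in genes}
        dist = {"soils-sediments/neutral": 0.8, "freshwater/water": 0.2}
        rows, _ = make_metadata(genes, default_habitat_tree(), {0: dist}, seed=3,
                                broader_only_fraction=0.0, clade_of_seq=clade_of)
        n_soil = sum(p == "soils-sediments/neutral" for _, p in rows)
        lo, hi = stats.binom.interval(0.99, 1000, 0.8)
        assert lo <= n_soil <= hi
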