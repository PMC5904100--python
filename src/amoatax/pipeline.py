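"""End-to-end convenience pipeline over a synthetic corpus.

simulate -> curate -> chimera screen -> cluster -> taxonomy -> signatures ->
habitat profiles, returning all intermediate products and optionally writing
every export format to a directory.  Tree inference is out of scope (an
external ML/Bayesian tool's job); the stage that needs a phylogeny uses the
simulated support tree over the generator's OTU representatives, exactly as a
real run would consume an externally inferred tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import chimera as chimera_mod
from . import clustering, curation, habitats, io, signatures, taxonomy
from .records import AlignedGene, RejectionLog
from .simulate import SimConfig, SimulatedDataset, default_habitat_tree, simulate_dataset


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    log: RejectionLog
    curated: list[AlignedGene]
    unique: list[AlignedGene]
    multiplicity: dict[str, int]
    reference_db: chimera_mod.ReferenceDB
    screen: chimera_mod.ScreenResult
    otus: list[clustering.OtuCluster]
    taxa: list[taxonomy.RankedTaxon]
    lineage_of_leaf: dict[str, str]
    signature_records: list[signatures.SignatureRecord]
    otu_signatures: list[signatures.OtuSignature]
    habitat_counts: dict[tuple[str, str], int]


def run_pipeline(config: SimConfig, outdir: str | Path | None = None) -> PipelineResult:
    dataset = simulate_dataset(config)
    log = RejectionLog()

    curated = curation.curate(dataset.raw_records, log=log)
    derep = curation.dereplicate(curated)
    study_of = {g.id: g.study for g in curated}

    db = chimera_mod.build_reference_db(derep.unique, derep.multiplicity, study_of)
    screen = chimera_mod.screen_all(derep.unique, db)

    dm = clustering.pairwise_distances(screen.kept)
    otus = clustering.average_neighbour(dm, 0.96)

    tree = dataset.tree
    collapsed = taxonomy.collapse_unsupported(tree)
    taxa = taxonomy.assign_ranks(collapsed, dataset.ground_truth.seeds)
    lineage_of_leaf = taxonomy.leaf_lineages(taxa)

    weights = signatures.fit_cai_weights([g for g in screen.kept], mode="iterative")
    sig_records = signatures.signature_table(screen.kept, weights)
    otu_of = clustering.otu_membership_map(otus)
    otu_sigs = signatures.otu_deviations(sig_records, otu_of)

    # link recovered OTUs to tree leaves through the generator representatives
    leaf_of_seq: dict[str, str] = {}
    rep_seq_to_leaf = {g.coding_seq: g.id for g in dataset.otu_representatives}
    members_by_otu: dict[str, list[str]] = {}
    seq_of = {g.id: g.coding_seq for g in screen.kept}
    for gid, otu in otu_of.items():
        members_by_otu.setdefault(otu, []).append(gid)
    otu_to_leaf = {}
    for otu, members in members_by_otu.items():
        for gid in members:
            leaf = rep_seq_to_leaf.get(seq_of[gid])
            if leaf is not None:
                otu_to_leaf[otu] = leaf
                break
    for gid, otu in otu_of.items():
        if otu in otu_to_leaf:
            leaf_of_seq[gid] = otu_to_leaf[otu]

    habitat_tree, assignments = habitats.load_categories(dataset.metadata_rows, default_habitat_tree())
    taxon_parent = {t.name: t.parent for t in taxa}
    # habitat counts over curated sequences (multiplicity-weighted by duplicates)
    kept_ids = set(otu_of)
    assign_kept = habitats.HabitatAssignment(
        {derep.duplicate_of.get(s, s): p for s, p in assignments.path_of.items() if derep.duplicate_of.get(s, s) in kept_ids}
    )
    counts = habitats.clade_frequency_table(
        lineage_of_leaf, taxon_parent, assign_kept, derep.multiplicity, seq_to_leaf=leaf_of_seq
    )

    result = PipelineResult(
        dataset, log, curated, derep.unique, derep.multiplicity, db, screen, otus,
        taxa, lineage_of_leaf, sig_records, otu_sigs, counts,
    )
    if outdir is not None:
        _write_exports(result, Path(outdir))
    return result


def _write_exports(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(outdir / "raw.fasta", res.dataset.raw_records)
    io.write_fasta(outdir / "curated.fasta", res.unique)
    io.write_tsv(outdir / "rejections.tsv", res.log.to_rows())
    io.write_tsv(
        outdir / "chimera_verdicts.tsv",
        [
            {
                "query": v.query_id, "parent_a": v.parent_a, "parent_b": v.parent_b,
                "breakpoint": v.breakpoint, "d": v.d, "h": v.h, "decision": v.decision,
            }
            for v in res.screen.verdicts
        ],
    )
    io.write_tsv(
        outdir / "otus.tsv",
        [
            {"otu_id": o.otu_id, "member": m, "representative": int(m == o.representative)}
            for o in res.otus
            for m in o.members
        ],
    )
    newick, lineage_tsv = taxonomy.export_taxonomy(res.taxa, taxonomy.collapse_unsupported(res.dataset.tree))
    (outdir / "taxonomy.nwk").write_text(newick + "\n")
    (outdir / "lineages.tsv").write_text(lineage_tsv)
    io.write_tsv(
        outdir / "signatures.tsv",
        [{"gene": r.gene_id, "gc": r.gc, "purine": r.purine, "nc": r.nc, "gcai": r.gcai} for r in res.signature_records],
    )
    io.write_tsv(
        outdir / "otu_signatures.tsv",
        [
            {"otu": s.otu_id, **{f"d_{m}": s.deviations[m] for m in signatures.METRICS},
             **{f"sd_{m}": s.sds[m] for m in signatures.METRICS}}
            for s in res.otu_signatures
        ],
    )
    taxon_parent = {t.name: t.parent for t in res.taxa}
    (outdir / "krona.tsv").write_text(habitats.export_krona(res.habitat_counts, taxon_parent))
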