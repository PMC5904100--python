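"""Reduction of raw records to in-frame, length-valid, stop-free fragments.

The screens mirror the standard pre-processing of a protein-coding marker-gene
corpus: drop ambiguous records, extract the longest stop-free reading frame
over both strands (rejecting anything shorter than 194 codons / 582 nt),
reject frameshifted fragments by pairwise alignment against the nearest
trusted reference, trim everything to the common 591-column frame, and
transiently dereplicate while keeping multiplicities for later abundance
rules.

All synthetic sequences share a single frame, so frame placement is columnar
bookkeeping; with real data an externally aligned input is accepted instead
(shipping an aligner is out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .records import (
    AlignedGene,
    DNA_ALPHABET,
    FRAME_COLUMNS,
    MIN_CODONS,
    RawRecord,
    RejectionLog,
    STOP_CODONS,
    revcomp,
)


def screen_alphabet(records: list[RawRecord], log: RejectionLog | None = None) -> list[RawRecord]:
    """Drop empty records and records with ambiguity codes (N etc.)."""
    log = log if log is not None else RejectionLog()
    kept = []
    for rec in records:
        seq = rec.seq.upper().replace("-", "")
        if not seq:
            log.reject(rec.id, "alphabet", "empty")
        elif set(seq) - DNA_ALPHABET:
            log.reject(rec.id, "alphabet", "ambiguous")
        else:
            kept.append(RawRecord(rec.id, seq, rec.source_study))
    return kept


def _longest_stop_free_run(seq: str, offset: int) -> tuple[int, int]:
    """(start, n_codons) of the longest stop-free codon run in this frame."""
    best_start, best_len = offset, 0
    run_start, run_len = offset, 0
    pos = offset
    while pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOP_CODONS:
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start, run_len = pos + 3, 0
        else:
            run_len += 1
        pos += 3
    if run_len > best_len:
        best_start, best_len = run_start, run_len
    return best_start, best_len


def extract_inframe(
    record: RawRecord, min_codons: int = MIN_CODONS, log: RejectionLog | None = None
) -> AlignedGene | None:
    """Longest stop-free in-frame fragment over all six frames.

    Ties between equally long fragments prefer the forward strand, then the
    lower frame offset.  Returns None (logged "no-orf") below ``min_codons``.
    """
    log = log if log is not None else RejectionLog()
    seq = record.seq.upper()
    candidates = []  # (n_codons, strand_rank, offset, start, oriented_seq, strand)
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for offset in range(3):
            start, n = _longest_stop_free_run(oriented, offset)
            candidates.append((n, 0 if strand == "+" else 1, offset, start, oriented, strand))
    n, _, offset, start, oriented, strand = max(candidates, key=lambda c: (c[0], -c[1], -c[2]))
    if n < min_codons:
        # classify why no qualifying frame exists: too short, a length
        # incompatible with whole codons (indel frameshift), or an
        # interrupting stop codon
        if len(seq) < 3 * min_codons:
            reason = "short"
        elif len(seq) % 3 != 0:
            reason = "frameshift"
        else:
            reason = "stop"
        log.reject(record.id, "inframe", reason)
        return None
    fragment = oriented[start : start + 3 * n]
    return AlignedGene(record.id, fragment, frame_offset=offset, strand=strand, study=record.source_study)


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -5.0
        a.extend_gap_score = -1.0
        try:
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
        _ALIGNER = a
    return _ALIGNER


@lru_cache(maxsize=8192)
def _kmer_set(seq: str, k: int = 8) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def nearest_reference(gene: AlignedGene, references: list[AlignedGene], k: int = 8) -> AlignedGene:
    """Reference with the highest shared-k-mer count (ties: smallest id)."""
    if not references:
        raise ValueError("empty reference set")
    q = _kmer_set(gene.coding_seq, k)
    return max(references, key=lambda r: (len(q & _kmer_set(r.coding_seq, k)), r.id))


def _internal_gap_runs(alignment) -> list[tuple[str, int]]:
    """Internal gap runs as (which sequence is gapped, run length)."""
    runs: list[tuple[str, int]] = []
    t_blocks, q_blocks = alignment.aligned
    # gaps in query between consecutive target blocks and vice versa
    for i in range(len(t_blocks) - 1):
        t_gap = int(t_blocks[i + 1][0] - t_blocks[i][1])
        q_gap = int(q_blocks[i + 1][0] - q_blocks[i][1])
        if t_gap and not q_gap:
            runs.append(("query", t_gap))
        elif q_gap and not t_gap:
            runs.append(("target", q_gap))
        elif t_gap and q_gap:  # simultaneous gaps: treat separately
            runs.append(("query", t_gap))
            runs.append(("target", q_gap))
    return runs


def screen_frameshifts(
    gene: AlignedGene,
    references: list[AlignedGene],
    max_indel: int = 3,
    log: RejectionLog | None = None,
) -> bool:
    """Pass iff the alignment to the nearest reference has only whole-codon gaps.

    Any internal gap run whose length is not a multiple of 3 marks a
    frameshift; whole-codon runs are accepted up to ``max_indel`` codons in
    total (biological codon insertions/deletions).
    """
    log = log if log is not None else RejectionLog()
    others = [r for r in references if r.id != gene.id]
    if not others:
        raise ValueError("empty reference set")
    ref = nearest_reference(gene, others)
    alignment = _aligner().align(ref.coding_seq, gene.coding_seq)[0]
    total_codon_gaps = 0
    for _, run in _internal_gap_runs(alignment):
        if run % 3 != 0:
            log.reject(gene.id, "frameshift", "frameshift")
            return False
        total_codon_gaps += run // 3
    if total_codon_gaps > max_indel:
        log.reject(gene.id, "frameshift", "too-many-codon-gaps")
        return False
    return True


def place_in_frame(gene: AlignedGene, references: list[AlignedGene]) -> AlignedGene:
    """Gap-pad a shorter gene into the common frame via its nearest full-length reference."""
    if len(gene.coding_seq) == FRAME_COLUMNS:
        return gene.with_alignment(gene.coding_seq)
    full = [r for r in references if len(r.coding_seq) == FRAME_COLUMNS]
    if not full:
        raise ValueError("no full-length reference available for frame placement")
    ref = nearest_reference(gene, full)
    alignment = _aligner().align(ref.coding_seq, gene.coding_seq)[0]
    t_blocks, q_blocks = alignment.aligned
    cols = ["-"] * FRAME_COLUMNS
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for off in range(te - ts):
            cols[ts + off] = gene.coding_seq[qs + off]
    return gene.with_alignment("".join(cols))


def global_trim(
    genes: list[AlignedGene],
    target_length: int = FRAME_COLUMNS,
    min_length: int = 3 * MIN_CODONS,
    references: list[AlignedGene] | None = None,
    log: RejectionLog | None = None,
) -> list[AlignedGene]:
    """Keep genes spanning the common frame; pad codon deletions, drop the rest.

    A gene longer than ``target_length`` is trimmed to the first
    ``target_length`` nucleotides of its fragment; a gene in
    [min_length, target_length) is retained gap-padded against the nearest
    full-length gene; anything shorter is excluded (logged "short").
    """
    log = log if log is not None else RejectionLog()
    refs = references if references is not None else [g for g in genes if len(g.coding_seq) >= target_length]
    kept: list[AlignedGene] = []
    for g in genes:
        seq = g.coding_seq
        if len(seq) > target_length:
            g = AlignedGene(
                g.id, seq[:target_length], g.frame_offset, g.strand, g.study, g.n_codon_deletions, habitat=g.habitat
            )
            seq = g.coding_seq
        if len(seq) == target_length:
            kept.append(g.with_alignment(seq))
        elif len(seq) >= min_length and len(seq) % 3 == 0:
            placed = place_in_frame(g, refs)
            n_del = (target_length - len(seq)) // 3
            kept.append(
                AlignedGene(
                    g.id, g.coding_seq, g.frame_offset, g.strand, g.study, n_del, placed.aligned_seq, g.habitat
                )
            )
        else:
            log.reject(g.id, "trim", "short")
    return kept


@dataclass
class DereplicationResult:
    unique: list[AlignedGene]
    multiplicity: dict[str, int]  # representative id -> copy count
    duplicate_of: dict[str, str]  # every input id -> representative id


def dereplicate(genes: list[AlignedGene]) -> DereplicationResult:
    """Collapse exact duplicates of coding_seq, keeping multiplicities."""
    by_seq: dict[str, list[AlignedGene]] = {}
    for g in genes:
        by_seq.setdefault(g.coding_seq, []).append(g)
    unique, mult, dup_of = [], {}, {}
    for members in by_seq.values():
        members = sorted(members, key=lambda g: g.id)
        rep = members[0]
        unique.append(rep)
        mult[rep.id] = len(members)
        for m in members:
            dup_of[m.id] = rep.id
    unique.sort(key=lambda g: g.id)
    return DereplicationResult(unique, mult, dup_of)


def curate(
    records: list[RawRecord],
    min_codons: int = MIN_CODONS,
    target_length: int = FRAME_COLUMNS,
    max_codon_deletions: int = 3,
    frameshift_references: list[AlignedGene] | None = None,
    log: RejectionLog | None = None,
) -> list[AlignedGene]:
    """Full curation chain: alphabet -> in-frame -> frameshift -> global trim.

    The frameshift screen uses ``frameshift_references`` when given, else the
    full-length fragments recovered from the batch itself.
    """
    log = log if log is not None else RejectionLog()
    clean = screen_alphabet(records, log)
    genes = [g for rec in clean if (g := extract_inframe(rec, min_codons, log)) is not None]
    refs = frameshift_references or [g for g in genes if len(g.coding_seq) >= target_length]
    if refs:
        genes = [g for g in genes if screen_frameshifts(g, refs, max_codon_deletions, log)]
    return global_trim(genes, target_length, 3 * min_codons, refs or None, log)
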