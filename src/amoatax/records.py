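"""Core record types shared across the pipeline.

Sequences travel through the pipeline as :class:`AlignedGene` objects: in-frame
nucleotide fragments laid out in a common 591-column coding frame (197 codons).
A gene with up to three biological codon deletions keeps a gapped
``aligned_seq`` of the full column count while its degapped ``coding_seq`` is
what the composition and codon-usage statistics see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

#: Length in columns of the common coding frame (the longest coding region
#: shared by nearly all full-length fragments of this marker gene).
FRAME_COLUMNS = 591

#: Minimum in-frame length accepted by curation: 194 codons = 582 nt, i.e. the
#: frame length minus up to three codon deletions.
MIN_CODONS = 194

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement on the ACGTN- alphabet."""
    return str(Seq(seq).reverse_complement())


def codons_of(seq: str) -> list[str]:
    """Split a degapped in-frame sequence into codons (drops a trailing partial codon)."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def has_internal_stop(seq: str) -> bool:
    """True if any codon before the last is a stop codon."""
    cds = codons_of(seq)
    return any(c in STOP_CODONS for c in cds[:-1]) or (bool(cds) and cds[-1] in STOP_CODONS)


@dataclass(frozen=True)
class RawRecord:
    """An uncurated nucleotide record as read from FASTA."""

    id: str
    seq: str
    source_study: str = ""


@dataclass(frozen=True)
class AlignedGene:
    """A curated in-frame fragment in the common coding frame.

    ``aligned_seq`` has exactly :data:`FRAME_COLUMNS` columns when frame
    placement has been performed ('-' marks codon deletions); until then it
    equals ``coding_seq``.
    """

    id: str
    coding_seq: str
    frame_offset: int = 0
    strand: str = "+"
    study: str = ""
    n_codon_deletions: int = 0
    aligned_seq: str = ""
    habitat: str = ""

    def __post_init__(self):
        if not self.aligned_seq:
            object.__setattr__(self, "aligned_seq", self.coding_seq)

    def with_alignment(self, aligned_seq: str) -> "AlignedGene":
        if aligned_seq.replace("-", "") != self.coding_seq:
            raise ValueError(f"{self.id}: aligned sequence does not degap to coding_seq")
        return replace(self, aligned_seq=aligned_seq)

    @property
    def length(self) -> int:
        return len(self.coding_seq)


@dataclass
class RejectionLog:
    """Per-stage record of why sequences were removed (id, stage, reason)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def reject(self, seq_id: str, stage: str, reason: str) -> None:
        self.entries.append((seq_id, stage, reason))

    def reasons_for(self, seq_id: str) -> list[str]:
        return [r for i, _, r in self.entries if i == seq_id]

    def to_rows(self) -> list[dict]:
        return [{"id": i, "stage": s, "reason": r} for i, s, r in self.entries]
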