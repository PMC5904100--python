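"""File-format helpers: FASTA (via Biopython), registries and tables as TSV."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AlignedGene, RawRecord


def write_fasta(path: str | Path, records: list[RawRecord] | list[AlignedGene]) -> None:
    seqs = []
    for r in records:
        seq = r.seq if isinstance(r, RawRecord) else r.aligned_seq
        desc = getattr(r, "source_study", "") or getattr(r, "study", "")
        seqs.append(SeqRecord(Seq(seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(seqs)


def read_fasta(path: str | Path) -> list[RawRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        study = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(RawRecord(rec.id, str(rec.seq).upper(), study))
    return out


def write_tsv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(path: str | Path, rows: list[tuple[str, str]]) -> None:
    write_tsv(path, [{"seqid": s, "habitat_path": p} for s, p in rows])


def read_metadata(path: str | Path) -> list[tuple[str, str]]:
    df = read_tsv(path)
    return list(zip(df["seqid"].astype(str), df["habitat_path"].astype(str)))


def write_phylip_distances(path: str | Path, ids: list[str], matrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{x:.6f}" for x in matrix[i])
            fh.write(f"{name}\t{row}\n")
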