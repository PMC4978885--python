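"""FASTA/FASTQ input-output built on Biopython (gzip-aware)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import SequenceRead


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, species: str = "") -> list[SequenceRead]:
    with _open(path) as fh:
        return [
            SequenceRead(
                read_id=rec.id,
                bases=str(rec.seq),
                qualities=rec.letter_annotations.get("phred_quality"),
                species=species,
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        quals = r.qualities if r.qualities is not None else [40] * len(r.bases)
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
        records.append(rec)
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fasta(path, species: str = "") -> list[SequenceRead]:
    with _open(path) as fh:
        return [
            SequenceRead(rec.id, str(rec.seq).upper(), None, species)
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
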