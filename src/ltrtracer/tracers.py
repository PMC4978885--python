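"""Reference panel of full-length LTR retrotransposons and tracer kmers.

Each full-length gypsy/copia element is decomposed into 100 bp windows
advancing by 15 bp (85 bp overlap between consecutive windows).  Mixed
into read clustering, these windows act as genomic "tracers": any cluster
they join inherits the parent element's superfamily and sublineage labels.
The 85-base identical overlap between consecutive tracers comfortably
exceeds the >=90%-identity / >=55%-overlap edge rule, so the tracer set of
a single element is guaranteed to form one connected component.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

KMER_SIZE = 100
KMER_STEP = 15  # 100 - 85 bp overlap

SUPERFAMILIES = ("gypsy", "copia")


@dataclass
class ReferenceElement:
    """A full-length LTR retrotransposon with its lineage labels."""

    element_id: str
    superfamily: str
    sublineage: str
    sequence: str
    family_alias: Optional[str] = None

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(
                f"element {self.element_id}: superfamily must be one of "
                f"{SUPERFAMILIES}, got {self.superfamily!r}"
            )
        if not self.sublineage:
            raise ValueError(f"element {self.element_id}: empty sublineage")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TracerKmer:
    """A tracer window of a reference element, carrying its parent's labels."""

    parent_id: str
    offset: int
    sequence: str
    superfamily: str
    sublineage: str

    @property
    def kmer_id(self) -> str:
        return f"{self.parent_id}|{self.offset}"


def _acgt_fraction(seq: str) -> float:
    counts = Counter(seq.upper())
    return sum(counts[b] for b in "ACGT") / max(len(seq), 1)


def load_panel(fasta: Path | str, metadata: Path | str) -> list[ReferenceElement]:
    """Load the reference panel FASTA with its element metadata table.

    ``metadata`` is a TSV with columns element_id, superfamily, sublineage
    and optionally family_alias.  Every FASTA record must have a metadata
    row; duplicate ids, missing metadata and sequences that are not
    predominantly ACGT are rejected with the offending id named.
    """
    meta = pd.read_csv(metadata, sep="\t", dtype=str)
    required = {"element_id", "superfamily", "sublineage"}
    if meta.empty:
        raise ValueError(f"metadata file {metadata} is empty")
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata file {metadata} lacks columns {sorted(required - set(meta.columns))}"
        )
    if meta["element_id"].duplicated().any():
        dup = meta.loc[meta["element_id"].duplicated(), "element_id"].iloc[0]
        raise ValueError(f"duplicate element_id in metadata: {dup}")
    meta = meta.set_index("element_id")

    panel: list[ReferenceElement] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id: {record.id}")
        seen.add(record.id)
        if record.id not in meta.index:
            raise ValueError(f"FASTA record {record.id} has no metadata row")
        row = meta.loc[record.id]
        seq = str(record.seq).upper()
        if _acgt_fraction(seq) < 0.95:
            raise ValueError(f"element {record.id}: sequence is not ACGT-heavy")
        alias = row.get("family_alias")
        panel.append(
            ReferenceElement(
                element_id=record.id,
                superfamily=row["superfamily"],
                sublineage=row["sublineage"],
                sequence=seq,
                family_alias=None if pd.isna(alias) else alias,
            )
        )
    if not panel:
        raise ValueError(f"no records found in panel FASTA {fasta}")
    missing = set(meta.index) - seen
    if missing:
        log.warning("metadata rows without FASTA records: %s", sorted(missing))
    counts = Counter(e.superfamily for e in panel)
    log.info(
        "loaded panel of %d elements (%s)",
        len(panel),
        ", ".join(f"{n} {sf}" for sf, n in sorted(counts.items())),
    )
    return panel


def kmer_count(length: int, k: int = KMER_SIZE, step: int = KMER_STEP) -> int:
    """Number of tracer kmers for an element of the given length."""
    if length < k:
        raise ValueError(f"element length {length} < kmer size {k}")
    return (length - k) // step + 1


def kmerize_element(
    element: ReferenceElement, k: int = KMER_SIZE, step: int = KMER_STEP
) -> list[TracerKmer]:
    """Decompose one element into tracer kmers at offsets 0, step, 2*step, ...

    Windows are emitted while they fit entirely inside the element; no
    extra 3'-anchored window is added when (L - k) is not a multiple of
    ``step``, so up to ``step - 1`` terminal bases may go untraced.
    """
    n = kmer_count(len(element), k, step)
    return [
        TracerKmer(
            parent_id=element.element_id,
            offset=i * step,
            sequence=element.sequence[i * step:i * step + k],
            superfamily=element.superfamily,
            sublineage=element.sublineage,
        )
        for i in range(n)
    ]


def kmerize_panel(
    panel: Sequence[ReferenceElement], k: int = KMER_SIZE, step: int = KMER_STEP
) -> tuple[list[TracerKmer], pd.DataFrame]:
    """Kmerize every panel element; returns (tracers, per-element count table)."""
    tracers: list[TracerKmer] = []
    rows = []
    for element in panel:
        kmers = kmerize_element(element, k, step)
        tracers.extend(kmers)
        rows.append(
            {
                "element_id": element.element_id,
                "superfamily": element.superfamily,
                "sublineage": element.sublineage,
                "length": len(element),
                "n_kmers": len(kmers),
            }
        )
    table = pd.DataFrame(rows)
    log.info("kmerized %d elements into %d tracer kmers", len(panel), len(tracers))
    return tracers, table


def write_tracer_fasta(tracers: Sequence[TracerKmer], path: Path | str) -> None:
    """Write tracers as FASTA with ids encoding parent and offset."""
    with open(Path(path), "w") as fh:
        for t in tracers:
            fh.write(f">{t.kmer_id}\n{t.sequence}\n")


def write_panel_fasta(panel: Sequence[ReferenceElement], path: Path | str) -> None:
    with open(Path(path), "w") as fh:
        for e in panel:
            fh.write(f">{e.element_id}\n{e.sequence}\n")


def write_panel_metadata(panel: Sequence[ReferenceElement], path: Path | str) -> None:
    rows = [
        {
            "element_id": e.element_id,
            "superfamily": e.superfamily,
            "sublineage": e.sublineage,
            "family_alias": e.family_alias or "",
        }
        for e in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
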