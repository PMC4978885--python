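"""Read filtering, organelle removal, and subsampling ahead of clustering.

Implements the quality rules applied to 2x100 bp Illumina data before
repeat clustering: reads shorter than 80 bases are dropped, terminal bases
below Q30 are trimmed, read ends are trimmed while a 4 bp sliding window
falls below mean Q25, chloroplast-derived reads are removed against an
organelle reference, and ~3 M single-end (R1) reads are randomly sampled
per species.  Rule order here is fixed as end-quality trim, then window
trim, then the length filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import revcomp


@dataclass
class SequenceRead:
    """A single (R1) sequencing read, optionally with Phred qualities."""

    read_id: str
    bases: str
    qualities: Optional[np.ndarray] = None
    species: str = ""

    def __post_init__(self):
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=np.int16)
            if len(self.qualities) != len(self.bases):
                raise ValueError(
                    f"read {self.read_id}: qualities length "
                    f"{len(self.qualities)} != bases length {len(self.bases)}"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimPolicy:
    """Quality-trimming thresholds (defaults match the study's criteria 2-4)."""

    min_length: int = 80
    end_quality: int = 30
    window: int = 4
    window_mean_quality: float = 25.0

    def __post_init__(self):
        if min(self.min_length, self.end_quality, self.window) < 0 or self.window_mean_quality < 0:
            raise ValueError("trim thresholds must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def quality_trim(read: SequenceRead, policy: TrimPolicy = TrimPolicy()) -> Optional[SequenceRead]:
    """Trim a read by end quality then sliding-window quality; drop if short.

    Returns the trimmed read, or None when the trimmed length falls below
    ``policy.min_length``.  Reads without qualities pass through unchanged
    (with a warning) so that synthetic FASTA input can be piped in.
    """
    if read.qualities is None:
        warnings.warn(
            f"read {read.read_id} has no qualities; passed through untrimmed",
            stacklevel=2,
        )
        return read
    q = read.qualities
    lo, hi = 0, len(q)  # retained slice [lo, hi)
    w = policy.window
    # iterate both rules to a fixed point so trimming is idempotent
    changed = True
    while changed and hi > lo:
        changed = False
        while lo < hi and q[lo] < policy.end_quality:
            lo += 1
        while hi > lo and q[hi - 1] < policy.end_quality:
            hi -= 1
        if hi - lo >= w:
            if q[lo:lo + w].mean() < policy.window_mean_quality:
                lo += 1
                changed = True
            elif q[hi - w:hi].mean() < policy.window_mean_quality:
                hi -= 1
                changed = True
    if hi - lo < policy.min_length:
        return None
    if lo == 0 and hi == len(q):
        return read
    return SequenceRead(
        read_id=read.read_id,
        bases=read.bases[lo:hi],
        qualities=q[lo:hi],
        species=read.species,
    )


def trim_reads(
    reads: Iterable[SequenceRead], policy: TrimPolicy = TrimPolicy()
) -> tuple[list[SequenceRead], int]:
    """Apply :func:`quality_trim` to a read stream; returns (kept, discarded)."""
    kept: list[SequenceRead] = []
    discarded = 0
    for read in reads:
        trimmed = quality_trim(read, policy)
        if trimmed is None:
            discarded += 1
        else:
            kept.append(trimmed)
    return kept, discarded


def _kmer_set(seqs: Iterable[str], k: int) -> set[str]:
    ref: set[str] = set()
    for seq in seqs:
        seq = seq.upper()
        rc = revcomp(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                ref.add(s[i:i + k])
    return ref


def filter_organelle(
    reads: Iterable[SequenceRead],
    organelle_seqs: Sequence[str],
    k: int = 31,
    min_hit_frac: float = 0.5,
) -> tuple[list[SequenceRead], int]:
    """Remove reads whose k-mers are contained in the organelle reference.

    A read is removed iff at least ``min_hit_frac`` of its k-mers occur in
    the organelle reference k-mer set (built over both strands) -- a
    containment screen standing in for read mapping against the chloroplast
    genome.  Reads shorter than ``k`` are retained.  Returns
    (retained reads, removed count).
    """
    if not organelle_seqs:
        raise ValueError("organelle reference is empty")
    ref = _kmer_set(organelle_seqs, k)
    retained: list[SequenceRead] = []
    removed = 0
    for read in reads:
        n_kmers = len(read.bases) - k + 1
        if n_kmers < 1:
            retained.append(read)
            continue
        hits = sum(1 for i in range(n_kmers) if read.bases[i:i + k] in ref)
        if hits / n_kmers >= min_hit_frac:
            removed += 1
        else:
            retained.append(read)
    return retained, removed


def sample_reads(
    reads: Sequence[SequenceRead], n: int = 3_000_000, seed: int = 0
) -> tuple[list[SequenceRead], int]:
    """Uniform sample without replacement of min(n, available) reads.

    Deterministic for a given seed; sampled reads keep their input order.
    When fewer than ``n`` reads are available the whole input is returned
    (mirroring datasets whose sampled size was reduced below the 3 M
    default).  Returns (sample, actual sampled count).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(reads):
        if n > len(reads):
            warnings.warn(
                f"requested {n} reads but only {len(reads)} available; "
                "returning all reads",
                stacklevel=2,
            )
        return list(reads), len(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx], n


@dataclass
class PreprocessReport:
    """Counts emitted alongside preprocessed reads."""

    input_count: int = 0
    trimmed_count: int = 0
    discarded_count: int = 0
    organelle_removed_count: int = 0
    sampled_count: int = 0
    extra: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = {
            "input_count": self.input_count,
            "trimmed_count": self.trimmed_count,
            "discarded_count": self.discarded_count,
            "organelle_removed_count": self.organelle_removed_count,
            "sampled_count": self.sampled_count,
            **self.extra,
        }
        with open(Path(path), "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in rows.items():
                fh.write(f"{key}\t{value}\n")
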