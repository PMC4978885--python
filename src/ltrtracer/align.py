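"""Pairwise overlap alignment used to decide similarity-graph edges.

Two sequences are joined in the repeat graph when their best overlap
(free-end-gap) alignment reaches >=90% identity over an overlap covering
>=55% of the shorter sequence -- the mgblast-style screen used by
graph-based repeat clustering of unassembled short reads.  Scoring is
match +1, mismatch -2, gap -3; identity is matches divided by aligned
columns (internal gaps included); the overlap length is the number of
aligned columns.  Both orientations of the second sequence are tried.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

#: default edge thresholds (fractions)
MIN_IDENTITY = 0.90
MIN_OVERLAP_FRAC = 0.55

# nucleotide encoding: A,C,G,T -> 0..3; anything else -> 4 (never matches)
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A0 C1 G2 T3, other 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTNN"[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1].copy()


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@njit(cache=True)
def overlap_align(a, b):  # pragma: no cover - exercised through wrappers
    """Best overlap alignment of code arrays ``a`` vs ``b``.

    Returns ``(score, matches, columns)`` for the maximum-score end-gap-free
    alignment.  Ties inside the DP prefer diagonal, then gap-in-b, then
    gap-in-a; endpoint ties prefer more matches, then more columns, then the
    earlier endpoint in scan order, so results are deterministic.
    """
    m = a.shape[0]
    n = b.shape[0]
    prev_s = np.zeros(n + 1, dtype=np.int32)
    prev_m = np.zeros(n + 1, dtype=np.int32)
    prev_c = np.zeros(n + 1, dtype=np.int32)
    cur_s = np.zeros(n + 1, dtype=np.int32)
    cur_m = np.zeros(n + 1, dtype=np.int32)
    cur_c = np.zeros(n + 1, dtype=np.int32)

    best_s = np.int32(-1)
    best_m = np.int32(0)
    best_c = np.int32(0)

    for i in range(1, m + 1):
        cur_s[0] = 0
        cur_m[0] = 0
        cur_c[0] = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1] and ai < 4:
                sub = 1
                hit = 1
            else:
                sub = -2
                hit = 0
            sd = prev_s[j - 1] + sub
            su = prev_s[j] - 3
            sl = cur_s[j - 1] - 3
            if sd >= su and sd >= sl:
                cur_s[j] = sd
                cur_m[j] = prev_m[j - 1] + hit
                cur_c[j] = prev_c[j - 1] + 1
            elif su >= sl:
                cur_s[j] = su
                cur_m[j] = prev_m[j]
                cur_c[j] = prev_c[j] + 1
            else:
                cur_s[j] = sl
                cur_m[j] = cur_m[j - 1]
                cur_c[j] = cur_c[j - 1] + 1
        # endpoint candidates: end of b (free trailing gap in b)
        if (cur_s[n] > best_s
                or (cur_s[n] == best_s
                    and (cur_m[n] > best_m
                         or (cur_m[n] == best_m and cur_c[n] > best_c)))):
            best_s = cur_s[n]
            best_m = cur_m[n]
            best_c = cur_c[n]
        for j in range(n + 1):
            prev_s[j] = cur_s[j]
            prev_m[j] = cur_m[j]
            prev_c[j] = cur_c[j]
    # endpoint candidates along the last row (free trailing gap in a)
    for j in range(1, n):
        if (prev_s[j] > best_s
                or (prev_s[j] == best_s
                    and (prev_m[j] > best_m
                         or (prev_m[j] == best_m and prev_c[j] > best_c)))):
            best_s = prev_s[j]
            best_m = prev_m[j]
            best_c = prev_c[j]
    if best_s < 0:
        return np.int32(0), np.int32(0), np.int32(0)
    return best_s, best_m, best_c


@njit(cache=True)
def edge_stats(a, b, b_rc):  # pragma: no cover - exercised through wrappers
    """Align ``a`` against ``b`` and its reverse complement; keep the better.

    Returns ``(score, matches, columns, strand)`` with strand +1 for the
    forward orientation, -1 for reverse; forward wins score ties.
    """
    fs, fm, fc = overlap_align(a, b)
    rs, rm, rc_ = overlap_align(a, b_rc)
    if rs > fs or (rs == fs and rm > fm):
        return rs, rm, rc_, -1
    return fs, fm, fc, 1


@njit(cache=True)
def qualifies(matches, columns, len_a, len_b, min_identity, min_overlap_frac):
    """Edge rule: identity >= min_identity and overlap >= frac of shorter seq."""
    if columns <= 0:
        return False
    shorter = min(len_a, len_b)
    if columns < min_overlap_frac * shorter:
        return False
    return matches >= min_identity * columns


@dataclass(frozen=True)
class SimilarityEdge:
    """A qualifying pairwise similarity (an edge of the repeat graph)."""

    id_a: str
    id_b: str
    identity: float
    overlap: int
    strand: int = 1

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.overlap < 1:
            raise ValueError("overlap must be >= 1")


def pair_similarity(
    a: str,
    b: str,
    min_identity: float = MIN_IDENTITY,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    id_a: str = "a",
    id_b: str = "b",
) -> Optional[SimilarityEdge]:
    """Return the similarity edge between two sequences, or None.

    The best overlap alignment of ``a`` against ``b`` and against the
    reverse complement of ``b`` is computed; an edge is returned iff
    identity >= ``min_identity`` (inclusive) and the aligned overlap spans
    at least ``min_overlap_frac`` of the shorter sequence (inclusive).
    """
    if len(a) < 20 or len(b) < 20:
        raise ValueError("pair_similarity requires sequences of >=20 bases")
    ca = encode(a)
    cb = encode(b)
    score, matches, columns, strand = edge_stats(ca, cb, revcomp_codes(cb))
    del score
    if qualifies(matches, columns, len(a), len(b), min_identity, min_overlap_frac):
        return SimilarityEdge(
            id_a=id_a,
            id_b=id_b,
            identity=float(matches) / float(columns),
            overlap=int(columns),
            strand=int(strand),
        )
    return None
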