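"""Graph-based repeat clustering of reads (plus tracer kmers).

Sampled reads and tracer kmers are clustered by an all-by-all similarity
rule (>=90% identity over >=55% overlap); clusters are the connected
components of the resulting graph.  Clusters holding at least 0.01% of the
sampled reads count toward the genomic repetitive fraction.  Tracer kmers
ride along for annotation only: they are excluded from the sampled-read
count, the cluster-size rule, and the fraction numerator.

Two execution paths produce the same partition on overlapping scales:

* an exact path that materializes the full similarity graph, prefiltering
  candidate pairs by a shared exact k-mer whose length is chosen so that
  any pair meeting the thresholds is guaranteed (pigeonhole on mismatch
  runs) to share one -- this equals the brute-force all-pairs graph;
* a union-find path for large read sets that only resolves connected
  components, generating candidate pairs from shared 11-mers (canonical,
  both strands) and skipping pairs already in one component.  The 11-mer
  prefilter is probabilistic per pair but component recovery is redundant
  (any path of qualifying edges connects a component), and passes repeat
  until no merges occur.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from numba import njit, types
from numba.typed import Dict as NumbaDict

from .align import (
    MIN_IDENTITY,
    MIN_OVERLAP_FRAC,
    edge_stats,
    encode,
    overlap_align,
    qualifies,
    revcomp_codes,
)
from .preprocess import SequenceRead
from .tracers import TracerKmer

log = logging.getLogger(__name__)

MIN_CLUSTER_FRAC = 0.0001  # >=0.01% of sampled reads
SCALE_PREFILTER_K = 11
EXACT_SIZE_LIMIT = 1500  # "auto" method switches to union-find above this


@dataclass
class RepeatCluster:
    """A connected set of sequences from the similarity graph."""

    cluster_id: str
    member_ids: tuple[str, ...]
    read_count: int
    tracer_counts: dict[str, int] = field(default_factory=dict)

    @property
    def tracer_total(self) -> int:
        return sum(self.tracer_counts.values())

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class FractionEstimate:
    """Repetitive-fraction estimate from one clustering run."""

    repetitive_fraction: float
    n_sampled: int
    min_cluster_size: int
    qualifying_clusters: list[str] = field(default_factory=list)


@dataclass
class ReplicateFractions:
    """Mean +/- SE of the repetitive fraction over replicate runs."""

    per_run: list[FractionEstimate]
    mean: float
    se: float


# ---------------------------------------------------------------------------
# sequence pool


class SequencePool:
    """Reads and tracers encoded into padded code matrices for the kernels."""

    def __init__(
        self,
        reads: Sequence[Union[SequenceRead, tuple[str, str]]],
        tracers: Sequence[TracerKmer] = (),
    ):
        ids: list[str] = []
        seqs: list[str] = []
        for r in reads:
            if isinstance(r, SequenceRead):
                ids.append(r.read_id)
                seqs.append(r.bases)
            else:
                rid, seq = r
                ids.append(rid)
                seqs.append(seq)
        n_reads = len(ids)
        tracer_sublineages: list[str] = []
        for t in tracers:
            ids.append(t.kmer_id)
            seqs.append(t.sequence)
            tracer_sublineages.append(t.sublineage)
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        self.ids = ids
        self.n_reads = n_reads
        self.n_tracers = len(tracers)
        self.tracer_sublineages = tracer_sublineages
        lens = np.array([len(s) for s in seqs], dtype=np.int32)
        if len(lens) and lens.min() < 20:
            raise ValueError("all sequences must be >= 20 bases")
        lmax = int(lens.max()) if len(lens) else 0
        mat = np.full((len(seqs), lmax), 5, dtype=np.uint8)
        rc_mat = np.full_like(mat, 5)
        for i, s in enumerate(seqs):
            codes = encode(s)
            mat[i, : lens[i]] = codes
            rc_mat[i, : lens[i]] = revcomp_codes(codes)
        self.mat = mat
        self.rc_mat = rc_mat
        self.lens = lens

    def __len__(self) -> int:
        return len(self.ids)

    def is_tracer(self, index: int) -> bool:
        return index >= self.n_reads

    def sublineage_of(self, index: int) -> str:
        return self.tracer_sublineages[index - self.n_reads]


def _kmer_instances(pool: SequencePool, k: int):
    """Canonical k-mer occurrence table for candidate-pair generation.

    Returns arrays (canon, seq, pos, fwd) sorted by (canon, seq) and
    deduplicated to one occurrence per (canonical k-mer, sequence) -- the
    lowest position wins.  ``fwd`` records whether the canonical form is
    the forward-strand k-mer at that position (used to orient the pair).
    """
    mat = pool.mat
    lens = pool.lens
    n, lmax = mat.shape
    w = lmax - k + 1
    empty = (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.uint8),
    )
    if w <= 0 or n == 0:
        return empty
    fw = np.zeros((n, w), dtype=np.int64)
    rv = np.zeros((n, w), dtype=np.int64)
    bad = np.zeros((n, w), dtype=bool)
    for i in range(k):
        col = mat[:, i:i + w].astype(np.int64)
        fw = fw * 4 + col
        rv = rv + (col << (2 * i))
        bad |= col >= 4
    rc = ((np.int64(1) << (2 * k)) - 1) - rv
    canon = np.minimum(fw, rc)
    is_fwd = (fw <= rc).astype(np.uint8)
    win_idx = np.arange(w)
    valid = (win_idx[None, :] <= (lens - k)[:, None]) & ~bad
    seq_idx = np.broadcast_to(np.arange(n)[:, None], (n, w))
    pos_idx = np.broadcast_to(win_idx[None, :], (n, w))
    canon_v = canon[valid]
    seq_v = seq_idx[valid].astype(np.int64)
    pos_v = pos_idx[valid].astype(np.int64)
    fwd_v = is_fwd[valid]
    order = np.lexsort((pos_v, seq_v, canon_v))
    canon_v, seq_v, pos_v, fwd_v = (
        canon_v[order], seq_v[order], pos_v[order], fwd_v[order]
    )
    keep = np.ones(len(canon_v), dtype=bool)
    if len(canon_v) > 1:
        keep[1:] = (np.diff(canon_v) != 0) | (np.diff(seq_v) != 0)
    return canon_v[keep], seq_v[keep], pos_v[keep], fwd_v[keep]


_SCREEN_K = 8
_SCREEN_SENTINEL = np.int64(1) << 40


def _screen_arrays(pool: SequencePool):
    """Per-sequence sorted 8-mer arrays (forward and reverse complement).

    Any alignment with identity >= i over V columns has at most
    floor((1-i)V) non-match columns splitting the matches into runs, and
    every run of length r contributes r-7 exact shared 8-mers; hence a
    qualifying pair shares at least matches - 7*(runs) 8-mers (multiset).
    Counting the intersection of sorted 8-mer arrays is a rigorous, cheap
    rejection screen ahead of the DP.  Invalid windows sort to a sentinel.
    """
    out = []
    for mat in (pool.mat, pool.rc_mat):
        n, lmax = mat.shape
        w = lmax - _SCREEN_K + 1
        if w <= 0:
            out.append(np.full((n, 1), _SCREEN_SENTINEL, dtype=np.int64))
            continue
        val = np.zeros((n, w), dtype=np.int64)
        bad = np.zeros((n, w), dtype=bool)
        for i in range(_SCREEN_K):
            col = mat[:, i:i + w].astype(np.int64)
            val = val * 4 + col
            bad |= col >= 4
        win_idx = np.arange(w)
        invalid = (win_idx[None, :] > (pool.lens - _SCREEN_K)[:, None]) | bad
        val[invalid] = _SCREEN_SENTINEL
        out.append(np.sort(val, axis=1))
    return out[0], out[1]


def _screen_thresholds(
    lmax: int, min_identity: float, min_overlap_frac: float
) -> np.ndarray:
    """Minimum shared-8-mer count implied by the edge rule, per shorter
    sequence length (0 disables the screen for that length)."""
    thr = np.zeros(lmax + 1, dtype=np.int64)
    for s in range(1, lmax + 1):
        v_min = max(1, math.ceil(min_overlap_frac * s))
        best = None
        for v in range(v_min, 4 * lmax + 1):
            errors = math.floor((1.0 - min_identity) * v)
            matches = math.ceil(min_identity * v)
            bound = matches - (_SCREEN_K - 1) * (errors + 1)
            best = bound if best is None else min(best, bound)
        thr[s] = max(0, best)
    return thr


@njit(cache=True)
def _shared_kmer_count(a8, b8):  # pragma: no cover
    i = 0
    j = 0
    count = 0
    na = a8.shape[0]
    nb = b8.shape[0]
    while i < na and j < nb:
        x = a8[i]
        y = b8[j]
        if x >= _SCREEN_SENTINEL or y >= _SCREEN_SENTINEL:
            break
        if x == y:
            count += 1
            i += 1
            j += 1
        elif x < y:
            i += 1
        else:
            j += 1
    return count


def _bucket_bounds(canon: np.ndarray):
    boundaries = np.flatnonzero(np.diff(canon)) + 1
    starts = np.concatenate(([0], boundaries)).astype(np.int64)
    ends = np.concatenate((boundaries, [len(canon)])).astype(np.int64)
    return starts, ends


def prefilter_guarantee_k(
    min_identity: float = MIN_IDENTITY,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    max_len: int = 100,
    min_len: int = 20,
) -> int:
    """Longest exact match guaranteed inside any qualifying alignment.

    Any alignment with identity >= ``min_identity`` over V columns has at
    most floor((1-id)*V) non-match columns splitting the matches into runs;
    the longest run (a shared exact k-mer) is at least
    ceil(matches / (errors + 1)).  Minimized over the possible overlap
    lengths V this gives a safe prefilter k-mer size.
    """
    v_min = max(1, math.ceil(min_overlap_frac * min_len))
    best = None
    for v in range(v_min, 2 * max_len + 1):
        errors = math.floor((1.0 - min_identity) * v)
        matches = v - errors
        run = math.ceil(matches / (errors + 1))
        best = run if best is None else min(best, run)
    return max(1, best)


# ---------------------------------------------------------------------------
# exact graph path


def build_similarity_graph(
    sequences: Union[SequencePool, Sequence, dict],
    min_identity: float = MIN_IDENTITY,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    prefilter_k: Optional[int] = None,
) -> nx.Graph:
    """The full all-by-all similarity graph (isolated sequences included).

    Candidate pairs are prefiltered by a shared canonical exact k-mer of a
    length guaranteed (see :func:`prefilter_guarantee_k`) to occur in any
    pair meeting the thresholds, so the edge set equals the brute-force
    all-pairs graph.
    """
    pool = _as_pool(sequences)
    if prefilter_k is None:
        prefilter_k = prefilter_guarantee_k(
            min_identity, min_overlap_frac, int(pool.lens.max()) if len(pool) else 100
        )
    graph = nx.Graph()
    for i, sid in enumerate(pool.ids):
        graph.add_node(
            sid,
            is_tracer=pool.is_tracer(i),
            sublineage=pool.sublineage_of(i) if pool.is_tracer(i) else None,
        )
    canon, items, _pos, _fwd = _kmer_instances(pool, prefilter_k)
    starts, ends = _bucket_bounds(canon)
    seen: set[int] = set()
    n = len(pool)
    for s, e in zip(starts, ends):
        members = items[s:e]
        for ai in range(len(members) - 1):
            a = int(members[ai])
            for bi in range(ai + 1, len(members)):
                b = int(members[bi])
                pair_key = a * n + b
                if pair_key in seen:
                    continue
                seen.add(pair_key)
                la, lb = int(pool.lens[a]), int(pool.lens[b])
                _, ma, co, st = edge_stats(
                    pool.mat[a, :la], pool.mat[b, :lb], pool.rc_mat[b, :lb]
                )
                if qualifies(ma, co, la, lb, min_identity, min_overlap_frac):
                    graph.add_edge(
                        pool.ids[a],
                        pool.ids[b],
                        identity=float(ma) / float(co),
                        overlap=int(co),
                        strand=int(st),
                    )
    return graph


def extract_clusters(graph: nx.Graph) -> list[RepeatCluster]:
    """Connected components of the similarity graph as repeat clusters.

    Clusters are ordered by decreasing size, ties broken by the
    lexicographically smallest member id, and labelled CL1, CL2, ...
    """
    groups = [sorted(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for i, members in enumerate(groups):
        read_count = 0
        tracer_counts: dict[str, int] = {}
        for m in members:
            attrs = graph.nodes[m]
            if attrs.get("is_tracer"):
                sub = attrs.get("sublineage") or "unknown"
                tracer_counts[sub] = tracer_counts.get(sub, 0) + 1
            else:
                read_count += 1
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{i + 1}",
                member_ids=tuple(members),
                read_count=read_count,
                tracer_counts=tracer_counts,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# union-find path for large inputs


@njit(cache=True)
def _find(parent, x):  # pragma: no cover
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def _try_pair(  # pragma: no cover
    u, m, fu, fm,
    mat, rc_mat, lens, parent, failed,
    fw8, rc8, thr,
    min_identity, min_overlap_frac,
):
    """Attempt one candidate pair; union on a qualifying alignment.

    The shared canonical k-mer supplies the relative orientation; a
    shared-8-mer counting screen (a rigorous implication of the edge rule)
    rejects hopeless pairs cheaply, and the full overlap DP applies the
    exact rule otherwise.  Deterministic failures are cached by member
    pair (with the orientation bit) so each pair is resolved once.
    """
    ru = _find(parent, u)
    rm = _find(parent, m)
    if ru == rm:
        return 0
    same = fu == fm
    lo = min(u, m)
    hi = max(u, m)
    key = (((np.int64(lo) << 27) | np.int64(hi)) << 1) | np.int64(1 if same else 0)
    if key in failed:
        return 0
    lu = lens[u]
    lm = lens[m]
    need = thr[min(lu, lm)]
    if need > 0:
        b8 = fw8[m] if same else rc8[m]
        if _shared_kmer_count(fw8[u], b8) < need:
            failed[key] = np.uint8(1)
            return 0
    if same:
        b = mat[m, :lm]
    else:
        b = rc_mat[m, :lm]
    a = mat[u, :lu]
    sc, ma, co = overlap_align(a, b)
    accepted = qualifies(ma, co, lu, lm, min_identity, min_overlap_frac)
    if not accepted:
        failed[key] = np.uint8(1)
    if accepted:
        if ru < rm:
            parent[rm] = ru
        else:
            parent[ru] = rm
        return 1
    return 0


@njit(cache=True)
def _union_pass(  # pragma: no cover
    starts, ends, items, fwds,
    mat, rc_mat, lens, parent, failed,
    fw8, rc8, thr,
    min_identity, min_overlap_frac, exhaustive, rbuf,
):
    n_union = 0
    for b in range(len(starts)):
        s = starts[b]
        e = ends[b]
        if e - s < 2:
            continue
        if exhaustive:
            # all cross-component member pairs; roots are buffered once per
            # bucket so same-component pairs cost one integer compare
            bsize = e - s
            for i in range(bsize):
                rbuf[i] = _find(parent, items[s + i])
            for i in range(bsize - 1):
                ri = rbuf[i]
                for j in range(i + 1, bsize):
                    if rbuf[j] == ri:
                        continue
                    n_union += _try_pair(
                        items[s + i], items[s + j], fwds[s + i], fwds[s + j],
                        mat, rc_mat, lens, parent, failed,
                        fw8, rc8, thr,
                        min_identity, min_overlap_frac,
                    )
        else:
            for t in range(s + 1, e):
                # anchor pair (star connectivity) and consecutive pair
                # (chains, e.g. the 85 bp tracer overlap ladder)
                n_union += _try_pair(
                    items[s], items[t], fwds[s], fwds[t],
                    mat, rc_mat, lens, parent, failed,
                    fw8, rc8, thr,
                    min_identity, min_overlap_frac,
                )
                if t - 1 > s:
                    n_union += _try_pair(
                        items[t - 1], items[t], fwds[t - 1], fwds[t],
                        mat, rc_mat, lens, parent, failed,
                        fw8, rc8, thr,
                        min_identity, min_overlap_frac,
                    )
    return n_union


def _components_unionfind(
    pool: SequencePool,
    min_identity: float,
    min_overlap_frac: float,
    prefilter_k: int = SCALE_PREFILTER_K,
    max_passes: int = 6,
) -> np.ndarray:
    """Component label per sequence via multi-pass union-find over buckets."""
    canon, items, _poss, fwds = _kmer_instances(pool, prefilter_k)
    starts, ends = _bucket_bounds(canon)
    parent = np.arange(len(pool), dtype=np.int64)
    failed = NumbaDict.empty(types.int64, types.uint8)
    max_bucket = int((ends - starts).max()) if len(starts) else 0
    rbuf = np.empty(max(max_bucket, 1), dtype=np.int64)
    fw8, rc8 = _screen_arrays(pool)
    lmax = int(pool.lens.max()) if len(pool) else 0
    thr = _screen_thresholds(lmax, min_identity, min_overlap_frac)
    # greedy passes (anchor + consecutive pairs) until stable, then
    # exhaustive within-bucket passes to catch the remaining bridges
    for exhaustive in (False, True):
        for i in range(max_passes):
            merged = _union_pass(
                starts, ends, items, fwds,
                pool.mat, pool.rc_mat, pool.lens, parent, failed,
                fw8, rc8, thr,
                min_identity, min_overlap_frac, exhaustive, rbuf,
            )
            log.debug(
                "union-find pass %d (exhaustive=%s): %d merges",
                i + 1, exhaustive, merged,
            )
            if merged == 0:
                break
    roots = np.empty(len(pool), dtype=np.int64)
    for i in range(len(pool)):
        roots[i] = _find(parent, i)
    return roots


def _clusters_from_roots(pool: SequencePool, roots: np.ndarray) -> list[RepeatCluster]:
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(int(r), []).append(i)
    keyed = []
    for members in groups.values():
        ids = sorted(pool.ids[i] for i in members)
        keyed.append((members, ids))
    keyed.sort(key=lambda g: (-len(g[1]), g[1][0]))
    clusters = []
    for i, (members, ids) in enumerate(keyed):
        read_count = 0
        tracer_counts: dict[str, int] = {}
        for m in members:
            if pool.is_tracer(m):
                sub = pool.sublineage_of(m)
                tracer_counts[sub] = tracer_counts.get(sub, 0) + 1
            else:
                read_count += 1
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{i + 1}",
                member_ids=tuple(ids),
                read_count=read_count,
                tracer_counts=tracer_counts,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# high-level API


def _as_pool(sequences) -> SequencePool:
    if isinstance(sequences, SequencePool):
        return sequences
    if isinstance(sequences, dict):
        return SequencePool(list(sequences.items()))
    return SequencePool(sequences)


def cluster_sequences(
    reads: Sequence[Union[SequenceRead, tuple[str, str]]],
    tracers: Sequence[TracerKmer] = (),
    min_identity: float = MIN_IDENTITY,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    method: str = "auto",
    prefilter_k: Optional[int] = None,
    community_detection: bool = False,
) -> list[RepeatCluster]:
    """Cluster reads (plus tracers) into repeat clusters.

    ``method`` is "exact" (full graph, brute-force-equivalent),
    "components" (union-find, large inputs), or "auto" (exact up to
    EXACT_SIZE_LIMIT sequences).  ``community_detection`` additionally
    splits each connected component by Louvain modularity (exact path
    only); it is off by default because the clustering rule itself is
    purely similarity-threshold based.
    """
    pool = SequencePool(reads, tracers)
    if method == "auto":
        method = "exact" if len(pool) <= EXACT_SIZE_LIMIT else "components"
    if method == "exact":
        graph = build_similarity_graph(
            pool, min_identity, min_overlap_frac, prefilter_k
        )
        if community_detection:
            return _louvain_clusters(graph)
        return extract_clusters(graph)
    if method == "components":
        if community_detection:
            raise ValueError("community_detection requires method='exact'")
        roots = _components_unionfind(
            pool, min_identity, min_overlap_frac, prefilter_k or SCALE_PREFILTER_K
        )
        return _clusters_from_roots(pool, roots)
    raise ValueError(f"unknown method {method!r}")


def _louvain_clusters(graph: nx.Graph) -> list[RepeatCluster]:
    groups = [
        sorted(c)
        for c in nx.algorithms.community.louvain_communities(graph, seed=0)
    ]
    groups.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for i, members in enumerate(groups):
        read_count = 0
        tracer_counts: dict[str, int] = {}
        for m in members:
            attrs = graph.nodes[m]
            if attrs.get("is_tracer"):
                sub = attrs.get("sublineage") or "unknown"
                tracer_counts[sub] = tracer_counts.get(sub, 0) + 1
            else:
                read_count += 1
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{i + 1}",
                member_ids=tuple(members),
                read_count=read_count,
                tracer_counts=tracer_counts,
            )
        )
    return clusters


def min_cluster_size(n_sampled: int, min_cluster_frac: float = MIN_CLUSTER_FRAC) -> int:
    """Smallest cluster (in reads) counted as repetitive: ceil(frac * n)."""
    return math.ceil(min_cluster_frac * n_sampled)


def repetitive_fraction(
    clusters: Sequence[RepeatCluster],
    n_sampled: int,
    min_cluster_frac: float = MIN_CLUSTER_FRAC,
    min_size: Optional[int] = None,
) -> FractionEstimate:
    """Fraction of sampled reads in clusters at or above the size threshold.

    ``n_sampled`` must be the number of reads (tracers excluded) that
    entered clustering; tracers never contribute to cluster size
    qualification or the numerator.
    """
    if n_sampled <= 0:
        raise ValueError("n_sampled must be > 0")
    threshold = min_size if min_size is not None else min_cluster_size(
        n_sampled, min_cluster_frac
    )
    qualifying = [c for c in clusters if c.read_count >= threshold]
    fraction = sum(c.read_count for c in qualifying) / n_sampled
    return FractionEstimate(
        repetitive_fraction=fraction,
        n_sampled=n_sampled,
        min_cluster_size=threshold,
        qualifying_clusters=[c.cluster_id for c in qualifying],
    )


def replicate_fraction(
    reads: Sequence[SequenceRead],
    tracers: Sequence[TracerKmer] = (),
    n_runs: int = 5,
    n_per_run: int = 3_000_000,
    seeds: Optional[Iterable[int]] = None,
    min_cluster_frac: float = MIN_CLUSTER_FRAC,
    **cluster_kwargs,
) -> ReplicateFractions:
    """Repetitive fraction over independent resampled clustering runs.

    Each run draws its own random subsample of ``n_per_run`` reads,
    clusters it (with tracers), and estimates the fraction; the summary is
    the arithmetic mean +/- SE (sample SD / sqrt(n_runs)).
    """
    from .preprocess import sample_reads

    if n_runs < 2:
        raise ValueError("need n_runs >= 2 for a standard error")
    seed_list = list(seeds) if seeds is not None else list(range(n_runs))
    if len(seed_list) != n_runs:
        raise ValueError("number of seeds must equal n_runs")
    estimates = []
    for seed in seed_list:
        sample, n_actual = sample_reads(reads, n_per_run, seed)
        clusters = cluster_sequences(sample, tracers, **cluster_kwargs)
        estimates.append(
            repetitive_fraction(clusters, n_actual, min_cluster_frac)
        )
    values = np.array([e.repetitive_fraction for e in estimates])
    return ReplicateFractions(
        per_run=estimates,
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / math.sqrt(n_runs)),
    )
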