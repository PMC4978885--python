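"""Synthetic reference panels, genomes, reads, and Brownian tip traits.

Every downstream stage of the pipeline is tested against simulated data
with known ground truth: a panel of full-length LTR-retrotransposon
exemplars with identical terminal repeats, species genomes assembled as a
random background carrying mutated copies of each family (shared ancestral
abundance plus optional lineage-specific amplification), uniform
low-coverage 100 bp single-end reads with a substitution error model, and
correlated Brownian-motion tip traits on a phylogeny for testing the
independent-contrasts machinery.

The mutation model is substitution-only by default so that identity
arithmetic against the 90%-identity clustering threshold stays exact; a
small-indel option is available behind a rate flag.  Family copies are
drawn around a family ancestor: each copy accumulates half the requested
copy-to-copy divergence, and the panel exemplar sits at the requested
panel divergence from the copies (clamped to be reachable, i.e.
``panel_divergence >= copy_divergence / 2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .align import decode, encode, revcomp_codes
from .preprocess import SequenceRead
from .tracers import SUPERFAMILIES, ReferenceElement

DEFAULT_READ_LENGTH = 100
#: LTR length convention for synthetic elements
MAX_LTR_LENGTH = 400


@dataclass(frozen=True)
class SimFamilySpec:
    """Simulation parameters for one TE family (sublineage exemplar)."""

    family_id: str
    superfamily: str
    sublineage: str
    element_length: int
    copies: int
    copy_divergence: float = 0.0
    panel_divergence: float = 0.0

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"superfamily must be one of {SUPERFAMILIES}")
        if self.element_length < 200:
            raise ValueError("element_length must be >= 200")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        for name in ("copy_divergence", "panel_divergence"):
            d = getattr(self, name)
            if not 0.0 <= d < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")


@dataclass
class SimGenome:
    """A simulated genome with its exact per-family composition."""

    sequence: str
    truth_table: dict[str, float]
    background_fraction: float
    #: (start, end, family_id) intervals of inserted copies, genome coords
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.truth_table.values()) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.truth_table.values()):
            raise ValueError("truth_table fractions must be nonnegative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadSimConfig:
    """Uniform-coverage single-end read simulation parameters."""

    n_reads: int
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.0
    quality_profile: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.quality_profile is not None:
            profile = np.asarray(self.quality_profile, dtype=np.int16)
            if len(profile) != self.read_length:
                raise ValueError("quality_profile length must equal read_length")
            object.__setattr__(self, "quality_profile", profile)


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(
    codes: np.ndarray,
    divergence: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> np.ndarray:
    """Substitute each base with probability ``divergence`` (always to a
    different base); optionally apply 1-3 bp indels at ``indel_rate``."""
    out = codes.copy()
    if divergence > 0:
        mask = rng.random(len(out)) < divergence
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        out[mask] = (out[mask] + shift) % 4
    if indel_rate > 0:
        pieces: list[np.ndarray] = []
        pos = 0
        events = np.flatnonzero(rng.random(len(out)) < indel_rate)
        for p in events:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pieces.append(out[pos:p])
                pos = min(p + size, len(out))
            else:  # insertion
                pieces.append(out[pos:p])
                pieces.append(_random_codes(rng, size))
                pos = p
        pieces.append(out[pos:])
        out = np.concatenate(pieces)
    return out


def simulate_reference_panel(
    specs: Sequence[SimFamilySpec], seed: int = 0
) -> list[ReferenceElement]:
    """Generate one full-length exemplar per family spec.

    Each element consists of two identical terminal repeats (LTRs) of
    length min(400, element_length // 4) flanking a random internal
    region.  Deterministic for a given seed.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    seen: set[str] = set()
    for spec in specs:
        if spec.family_id in seen:
            raise ValueError(f"duplicate family_id: {spec.family_id}")
        seen.add(spec.family_id)
    rng = np.random.default_rng(seed)
    panel = []
    for spec in specs:
        ltr_len = min(MAX_LTR_LENGTH, spec.element_length // 4)
        ltr = _random_codes(rng, ltr_len)
        internal = _random_codes(rng, spec.element_length - 2 * ltr_len)
        seq = decode(np.concatenate([ltr, internal, ltr]))
        panel.append(
            ReferenceElement(
                element_id=spec.family_id,
                superfamily=spec.superfamily,
                sublineage=spec.sublineage,
                sequence=seq,
            )
        )
    return panel


def simulate_species_genome(
    panel: Sequence[ReferenceElement],
    specs: Sequence[SimFamilySpec],
    background_length: int,
    seed: int = 0,
    max_insert_bases: Optional[int] = None,
    indel_rate: float = 0.0,
    min_spacing: int = 0,
) -> SimGenome:
    """Assemble a genome: random background plus mutated family copies.

    Copies of each family are derived from the panel exemplar through a
    family ancestor so that copy-to-copy divergence averages
    ``copy_divergence`` and copy-to-exemplar divergence averages
    ``panel_divergence``; they are spliced into the background at uniform
    random positions.  The truth table records the exact fraction of
    genome bases contributed by each family.

    ``min_spacing`` guarantees at least that many background bases between
    consecutive insertions (dispersed placement).  With the default 0,
    copies may insert adjacently or at the same point, producing chimeric
    junctions whose reads chain otherwise unrelated families into one
    component -- realistic, but it blurs the per-family ground truth that
    recovery experiments need.
    """
    by_id = {e.element_id: e for e in panel}
    for spec in specs:
        if spec.family_id not in by_id:
            raise ValueError(f"family {spec.family_id} not present in panel")
    rng = np.random.default_rng(seed)
    background = _random_codes(rng, background_length)

    copies: list[tuple[str, np.ndarray]] = []
    for spec in specs:
        exemplar = encode(by_id[spec.family_id].sequence)
        half = spec.copy_divergence / 2.0
        ancestor = _mutate(exemplar, max(0.0, spec.panel_divergence - half), rng)
        for _ in range(spec.copies):
            copies.append((spec.family_id, _mutate(ancestor, half, rng, indel_rate)))

    total_insert = sum(len(c) for _, c in copies)
    cap = max_insert_bases if max_insert_bases is not None else 20 * background_length
    if total_insert > cap:
        raise ValueError(
            f"total inserted bases {total_insert} exceed the cap {cap}"
        )

    n_copies = len(copies)
    if min_spacing > 0 and n_copies > 1:
        slack = background_length - (n_copies - 1) * min_spacing
        if slack < 0:
            raise ValueError(
                f"background too short for {n_copies} insertions with "
                f"min_spacing={min_spacing}"
            )
        base = np.sort(rng.integers(0, slack + 1, size=n_copies))
        positions = base + min_spacing * np.arange(n_copies)
    else:
        positions = np.sort(rng.integers(0, background_length + 1, size=n_copies))
    order = rng.permutation(n_copies)  # which copy goes at which position
    pieces: list[np.ndarray] = []
    intervals: list[tuple[int, int, str]] = []
    prev = 0
    out_pos = 0
    for pos, idx in zip(positions, order):
        pieces.append(background[prev:pos])
        out_pos += pos - prev
        fam, copy_codes = copies[idx]
        pieces.append(copy_codes)
        intervals.append((out_pos, out_pos + len(copy_codes), fam))
        out_pos += len(copy_codes)
        prev = pos
    pieces.append(background[prev:])
    genome_codes = np.concatenate(pieces) if pieces else background
    total = len(genome_codes)

    fam_bases: dict[str, int] = {spec.family_id: 0 for spec in specs}
    for start, end, fam in intervals:
        fam_bases[fam] += end - start
    truth = {fam: bases / total for fam, bases in fam_bases.items()}
    return SimGenome(
        sequence=decode(genome_codes),
        truth_table=truth,
        background_fraction=background_length / total,
        intervals=intervals,
    )


def read_origins(
    genome: SimGenome, starts: np.ndarray
) -> list[str]:
    """Family label of the copy each read start position falls inside
    (empty string for background)."""
    if not genome.intervals:
        return [""] * len(starts)
    ivs = sorted(genome.intervals)
    lo = np.array([s for s, _, _ in ivs])
    hi = np.array([e for _, e, _ in ivs])
    fams = [f for _, _, f in ivs]
    idx = np.searchsorted(lo, starts, side="right") - 1
    out = []
    for s, i in zip(starts, idx):
        if i >= 0 and s < hi[i]:
            out.append(fams[i])
        else:
            out.append("")
    return out


def simulate_reads(
    genome: SimGenome,
    cfg: ReadSimConfig,
    species: str = "sim",
    return_starts: bool = False,
):
    """Simulate uniform single-end reads from a genome.

    Start positions are uniform over the genome, strand is chosen
    uniformly, substitution errors are applied at ``cfg.error_rate``, and
    qualities come from ``cfg.quality_profile`` (default: flat Q38).
    Sampling is with replacement, so more reads than genome positions may
    be requested.  Returns a list of :class:`SequenceRead`; with
    ``return_starts`` also the genomic start coordinates (for ground-truth
    read-origin accounting).
    """
    codes = encode(genome.sequence)
    L = cfg.read_length
    if len(codes) < L:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    starts = rng.integers(0, len(codes) - L + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    profile = (
        cfg.quality_profile
        if cfg.quality_profile is not None
        else np.full(L, 38, dtype=np.int16)
    )
    reads: list[SequenceRead] = []
    window = np.arange(L)
    chunk = 200_000
    counter = 0
    for off in range(0, n, chunk):
        sub_starts = starts[off:off + chunk]
        sub_strands = strands[off:off + chunk]
        block = codes[sub_starts[:, None] + window]
        if cfg.error_rate > 0:
            mask = rng.random(block.shape) < cfg.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            block[mask] = (block[mask] + shift) % 4
        for row, strand in zip(block, sub_strands):
            if strand:
                row = revcomp_codes(row)
            reads.append(
                SequenceRead(
                    read_id=f"{species}.r{counter}",
                    bases=decode(row),
                    qualities=profile,
                    species=species,
                )
            )
            counter += 1
    if return_starts:
        return reads, starts
    return reads


def simulate_brownian_traits(
    tree: dendropy.Tree,
    sigma: float,
    true_correlation: float,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Evolve two correlated Brownian traits along a tree.

    Per-branch increments are bivariate normal with variance
    ``sigma**2 * branch_length`` and increment correlation
    ``true_correlation``.  Returns two tip-label -> value maps.
    """
    if not -1.0 <= true_correlation <= 1.0:
        raise ValueError("true_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    r = true_correlation
    values: dict[int, tuple[float, float]] = {}
    x: dict[str, float] = {}
    y: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = (0.0, 0.0)
        else:
            b = node.edge.length
            if b is None or b <= 0:
                raise ValueError("every branch must have positive length")
            px, py = values[id(node.parent_node)]
            z1, z2 = rng.standard_normal(2)
            scale = sigma * math.sqrt(b)
            dx = scale * z1
            dy = scale * (r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * z2)
            values[id(node)] = (px + dx, py + dy)
        if node.is_leaf():
            label = node.taxon.label
            x[label], y[label] = values[id(node)]
    return x, y


#: background length of the study-like scenario (bases)
STUDY_BACKGROUND_LENGTH = 2_650_000
#: dispersed placement spacing of the study-like scenario (bases); keeps
#: per-family ground truth identifiable (no chimeric TE-TE junctions)
STUDY_MIN_SPACING = 500


def study_like_specs(amplified: Optional[dict[str, float]] = None) -> list[SimFamilySpec]:
    """Family specs emulating the study conditions at desk scale.

    Five sublineages (three gypsy, two copia) whose element lengths span
    the 4.3-16.2 kb range of the reference panel, with a ~4.5-fold
    gypsy-to-copia base ratio, young copies (2% copy-to-copy divergence)
    and a 3% divergence from the panel exemplars.  Together with a
    2.65 Mb background the genome is ~8.8 Mb with a ~70% repetitive
    fraction, so 50 k 100 bp reads give ~0.6x coverage -- the
    low-coverage regime the clustering method assumes.

    ``amplified`` maps family_id -> copy-number multiplier, to emulate
    lineage-specific amplification in one species.
    """
    base = [
        SimFamilySpec("RLG_A", "gypsy", "A", 14000, 180, 0.02, 0.03),
        SimFamilySpec("RLG_B", "gypsy", "B", 9200, 160, 0.02, 0.03),
        SimFamilySpec("RLG_C", "gypsy", "C", 6450, 160, 0.02, 0.03),
        SimFamilySpec("RLC_1", "copia", "1", 8300, 100, 0.02, 0.03),
        SimFamilySpec("RLC_2", "copia", "2", 4700, 60, 0.02, 0.03),
    ]
    if amplified:
        out = []
        for spec in base:
            factor = amplified.get(spec.family_id, 1.0)
            out.append(
                SimFamilySpec(
                    spec.family_id,
                    spec.superfamily,
                    spec.sublineage,
                    spec.element_length,
                    int(round(spec.copies * factor)),
                    spec.copy_divergence,
                    spec.panel_divergence,
                )
            )
        return out
    return base


def random_bifurcating_tree(
    n_tips: int,
    seed: int = 0,
    min_branch: float = 0.2,
    max_branch: float = 1.2,
) -> dendropy.Tree:
    """A random rooted bifurcating tree with uniform random branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    nodes = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            child.edge.length = float(rng.uniform(min_branch, max_branch))
            parent.add_child(child)
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree
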