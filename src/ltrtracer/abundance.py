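"""Tracer-based cluster annotation and per-sublineage genomic abundance.

A cluster inherits the sublineage whose tracer kmers dominate it
(majority rule); clusters where the top sublineage holds less than 80% of
the tracers, or whose tracers mix superfamilies, are flagged as ambiguous
rather than silently resolved, making chaining artefacts visible.  The
genomic abundance of a sublineage in one clustering run is the fraction
of sampled reads falling in qualifying clusters annotated to it; tracers
never enter the numerators.  Replicate runs are summarized as
mean +/- SE per sublineage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import (
    MIN_CLUSTER_FRAC,
    FractionEstimate,
    RepeatCluster,
    cluster_sequences,
    min_cluster_size,
    repetitive_fraction,
)
from .preprocess import SequenceRead, sample_reads
from .tracers import TracerKmer

UNASSIGNED = "unassigned"
PURITY_THRESHOLD = 0.8


@dataclass
class ClusterAnnotation:
    """Sublineage call for one repeat cluster, from its tracer content."""

    cluster_id: str
    superfamily: str
    sublineage: str
    tracer_total: int
    tracer_breakdown: dict[str, int] = field(default_factory=dict)
    ambiguity_flag: bool = False


@dataclass
class SublineageProfile:
    """Per-sublineage genome proportions for one species and one run."""

    species: str
    proportions: dict[str, float]
    superfamily_of: dict[str, str]
    superfamily_totals: dict[str, float]
    unassigned_repeat: float
    repetitive_fraction: float
    n_sampled: int


def annotate_cluster(
    cluster: RepeatCluster,
    sublineage_superfamily: Mapping[str, str],
    purity_threshold: float = PURITY_THRESHOLD,
) -> ClusterAnnotation:
    """Assign a cluster to the sublineage with the most tracer kmers.

    The ambiguity flag is set when the top sublineage holds less than
    ``purity_threshold`` of the cluster's tracers (strict inequality) or
    when the tracers span both superfamilies.  A cluster without tracers
    is unassigned.
    """
    breakdown = dict(cluster.tracer_counts)
    total = sum(breakdown.values())
    if total == 0:
        return ClusterAnnotation(
            cluster_id=cluster.cluster_id,
            superfamily=UNASSIGNED,
            sublineage=UNASSIGNED,
            tracer_total=0,
        )
    top = max(sorted(breakdown), key=lambda s: breakdown[s])
    superfamilies = {sublineage_superfamily[s] for s in breakdown}
    flagged = (breakdown[top] / total < purity_threshold) or len(superfamilies) > 1
    return ClusterAnnotation(
        cluster_id=cluster.cluster_id,
        superfamily=sublineage_superfamily[top],
        sublineage=top,
        tracer_total=total,
        tracer_breakdown=breakdown,
        ambiguity_flag=flagged,
    )


def sublineage_profile(
    clusters: Sequence[RepeatCluster],
    n_sampled: int,
    sublineage_superfamily: Mapping[str, str],
    species: str = "",
    min_cluster_frac: float = MIN_CLUSTER_FRAC,
    min_size: Optional[int] = None,
    purity_threshold: float = PURITY_THRESHOLD,
) -> SublineageProfile:
    """Per-sublineage genome proportions from one clustering run.

    Only clusters passing the minimum-size rule contribute; each
    contributes its read count to the sublineage it is annotated to (or
    to the unassigned-repeat pool when it holds no tracers).  By
    construction the annotated proportions plus the unassigned repeat
    proportion equal the run's repetitive fraction exactly.
    """
    if n_sampled <= 0:
        raise ValueError("n_sampled must be > 0")
    threshold = min_size if min_size is not None else min_cluster_size(
        n_sampled, min_cluster_frac
    )
    proportions = {s: 0.0 for s in sublineage_superfamily}
    unassigned_reads = 0
    repetitive_reads = 0
    for cluster in clusters:
        if cluster.read_count < threshold:
            continue
        repetitive_reads += cluster.read_count
        ann = annotate_cluster(cluster, sublineage_superfamily, purity_threshold)
        if ann.sublineage == UNASSIGNED:
            unassigned_reads += cluster.read_count
        else:
            proportions[ann.sublineage] += cluster.read_count / n_sampled
    totals = {"gypsy": 0.0, "copia": 0.0}
    for sub, prop in proportions.items():
        totals[sublineage_superfamily[sub]] += prop
    return SublineageProfile(
        species=species,
        proportions=proportions,
        superfamily_of=dict(sublineage_superfamily),
        superfamily_totals=totals,
        unassigned_repeat=unassigned_reads / n_sampled,
        repetitive_fraction=repetitive_reads / n_sampled,
        n_sampled=n_sampled,
    )


def superfamily_ratio(profile: SublineageProfile) -> float:
    """Gypsy-to-copia fold ratio of superfamily totals (NaN if copia is 0)."""
    gypsy = profile.superfamily_totals.get("gypsy", 0.0)
    copia = profile.superfamily_totals.get("copia", 0.0)
    if copia == 0:
        warnings.warn("copia total is zero; gypsy:copia ratio undefined", stacklevel=2)
        return math.nan
    return gypsy / copia


def aggregate_replicates(profiles: Sequence[SublineageProfile]) -> pd.DataFrame:
    """Mean +/- SE per sublineage over replicate clustering runs.

    Returns a table with columns species, superfamily, sublineage, mean,
    se, n_runs (SE = sample SD / sqrt(n_runs)).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicate profiles")
    sublineages = sorted(profiles[0].proportions)
    for p in profiles[1:]:
        if sorted(p.proportions) != sublineages:
            raise ValueError("replicates have mismatched sublineage sets")
    n = len(profiles)
    rows = []
    for sub in sublineages:
        values = np.array([p.proportions[sub] for p in profiles])
        rows.append(
            {
                "species": profiles[0].species,
                "superfamily": profiles[0].superfamily_of[sub],
                "sublineage": sub,
                "mean": float(values.mean()),
                "se": float(values.std(ddof=1) / math.sqrt(n)),
                "n_runs": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReplicateRun:
    """One replicate clustering run: clusters + fraction + profile."""

    seed: int
    fraction: FractionEstimate
    profile: SublineageProfile


def replicate_profiles(
    reads: Sequence[SequenceRead],
    tracers: Sequence[TracerKmer],
    n_runs: int = 5,
    n_per_run: int = 3_000_000,
    seeds: Optional[Iterable[int]] = None,
    species: str = "",
    min_cluster_frac: float = MIN_CLUSTER_FRAC,
    **cluster_kwargs,
) -> list[ReplicateRun]:
    """Run n_runs independent sample-and-cluster replicates with profiles."""
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    seed_list = list(seeds) if seeds is not None else list(range(n_runs))
    if len(seed_list) != n_runs:
        raise ValueError("number of seeds must equal n_runs")
    sub_sf = {t.sublineage: t.superfamily for t in tracers}
    runs = []
    for seed in seed_list:
        sample, n_actual = sample_reads(reads, n_per_run, seed)
        clusters = cluster_sequences(sample, tracers, **cluster_kwargs)
        fraction = repetitive_fraction(clusters, n_actual, min_cluster_frac)
        profile = sublineage_profile(
            clusters, n_actual, sub_sf, species=species,
            min_cluster_frac=min_cluster_frac,
        )
        runs.append(ReplicateRun(seed=seed, fraction=fraction, profile=profile))
    return runs


def profile_table(runs: Sequence[ReplicateRun]) -> pd.DataFrame:
    """Replicate mean +/- SE table per sublineage (bar-chart ready)."""
    return aggregate_replicates([r.profile for r in runs])
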