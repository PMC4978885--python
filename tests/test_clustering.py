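"""Similarity graph construction, cluster extraction, fraction estimation."""

import math

import networkx as nx
import numpy as np
import pytest

from ltrtracer.align import pair_similarity, revcomp
from ltrtracer.clustering import (
    FractionEstimate,
    RepeatCluster,
    SequencePool,
    _components_unionfind,
    build_similarity_graph,
    cluster_sequences,
    extract_clusters,
    min_cluster_size,
    prefilter_guarantee_k,
    repetitive_fraction,
    replicate_fraction,
)
from ltrtracer.preprocess import SequenceRead
from ltrtracer.synthetic import (
    ReadSimConfig,
    SimFamilySpec,
    simulate_reads,
    simulate_reference_panel,
    simulate_species_genome,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_graph(seqs, **kwargs):
    """All-pairs oracle: align every pair without any prefilter."""
    graph = nx.Graph()
    graph.add_nodes_from(sid for sid, _ in seqs)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            (ida, a), (idb, b) = seqs[i], seqs[j]
            if pair_similarity(a, b, **kwargs) is not None:
                graph.add_edge(ida, idb)
    return graph


def _family_reads(rng, n_reads, ref_len=1500, divergence=0.03, prefix="fam"):
    """Reads drawn from mutated copies of one reference sequence."""
    ref = _random_seq(rng, ref_len)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, ref_len - 100 + 1))
        window = list(ref[start:start + 100])
        for p in np.flatnonzero(rng.random(100) < divergence):
            window[p] = "ACGT"["ACGT".index(window[p]) - 1]
        seq = "".join(window)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"{prefix}{i}", seq))
    return reads


class TestSimilarityGraph:
    def test_three_identical_reads_form_a_triangle(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 100)
        graph = build_similarity_graph([("a", s), ("b", s), ("c", s)])
        assert graph.number_of_edges() == 3

    def test_unrelated_sources_are_disconnected(self):
        rng = np.random.default_rng(1)
        ref1, ref2 = _random_seq(rng, 500), _random_seq(rng, 500)
        seqs = [(f"x{i}", ref1[i * 40:i * 40 + 100]) for i in range(5)]
        seqs += [(f"y{i}", ref2[i * 40:i * 40 + 100]) for i in range(5)]
        graph = build_similarity_graph(seqs)
        comps = list(nx.connected_components(graph))
        xs = {n for c in comps for n in c if n.startswith("x")}
        assert not any(
            graph.has_edge(a, b) for a in xs for b in graph if b.startswith("y")
        )

    def test_prefiltered_graph_equals_brute_force(self):
        rng = np.random.default_rng(2)
        seqs = _family_reads(rng, 200, divergence=0.03)
        fast = build_similarity_graph(seqs)
        brute = brute_force_graph(seqs)
        assert set(fast.nodes) == set(brute.nodes)
        assert set(map(frozenset, fast.edges)) == set(map(frozenset, brute.edges))

    def test_reverse_complementing_reads_leaves_graph_unchanged(self):
        rng = np.random.default_rng(3)
        seqs = _family_reads(rng, 60, divergence=0.02)
        flipped = [
            (sid, revcomp(s) if i % 3 == 0 else s)
            for i, (sid, s) in enumerate(seqs)
        ]
        g1 = build_similarity_graph(seqs)
        g2 = build_similarity_graph(flipped)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_guarantee_k_is_conservative(self):
        # the pigeonhole bound at the default thresholds
        assert prefilter_guarantee_k(0.90, 0.55, 100) <= 9


class TestExtractClusters:
    def test_isolated_sequences_are_singletons(self):
        rng = np.random.default_rng(4)
        seqs = [(f"s{i}", _random_seq(rng, 100)) for i in range(5)]
        graph = build_similarity_graph(seqs)
        clusters = extract_clusters(graph)
        assert len(clusters) == 5
        assert all(c.size == 1 and c.read_count == 1 for c in clusters)

    def test_two_diverged_families_give_two_clusters(self):
        rng = np.random.default_rng(5)
        # deep coverage of short references so each family chains fully
        fam1 = _family_reads(rng, 60, ref_len=500, divergence=0.02, prefix="a")
        fam2 = _family_reads(rng, 60, ref_len=500, divergence=0.02, prefix="b")
        clusters = cluster_sequences(fam1 + fam2, method="exact")
        big = [c for c in clusters if c.size > 1]
        assert len(big) == 2
        for c in big:
            prefixes = {m[0] for m in c.member_ids}
            assert len(prefixes) == 1

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(6)
        s1 = _random_seq(rng, 100)
        s2 = _random_seq(rng, 100)
        seqs = [("b1", s1), ("b2", s1), ("a1", s2), ("a2", s2), ("z", _random_seq(rng, 100))]
        clusters = cluster_sequences(seqs, method="exact")
        assert [c.cluster_id for c in clusters] == ["CL1", "CL2", "CL3"]
        # size ties broken by smallest member id
        assert clusters[0].member_ids == ("a1", "a2")
        assert clusters[1].member_ids == ("b1", "b2")


class TestUnionFindPath:
    def test_partition_matches_exact_graph(self):
        rng = np.random.default_rng(7)
        seqs = (_family_reads(rng, 150, divergence=0.03, prefix="a")
                + _family_reads(rng, 100, divergence=0.03, prefix="b")
                + [(f"bg{i}", _random_seq(rng, 100)) for i in range(50)])
        exact = cluster_sequences(seqs, method="exact")
        fast = cluster_sequences(seqs, method="components")
        exact_parts = sorted(c.member_ids for c in exact)
        fast_parts = sorted(c.member_ids for c in fast)
        assert exact_parts == fast_parts

    def test_clusters_partition_the_input(self):
        rng = np.random.default_rng(8)
        seqs = _family_reads(rng, 120, divergence=0.04)
        clusters = cluster_sequences(seqs, method="components")
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(sid for sid, _ in seqs)


class TestFraction:
    def test_min_cluster_size_at_3m_reads_is_300(self):
        assert min_cluster_size(3_000_000) == 300

    def test_min_cluster_size_scales_with_dataset(self):
        # a 2.4 M-read dataset implies a 240-read threshold
        assert min_cluster_size(2_400_000) == 240
        assert min_cluster_size(50_000) == 5

    def test_subthreshold_cluster_contributes_nothing(self):
        clusters = [RepeatCluster("CL1", tuple(f"r{i}" for i in range(299)), 299)]
        est = repetitive_fraction(clusters, 3_000_000)
        assert est.repetitive_fraction == 0.0
        assert est.min_cluster_size == 300

    def test_single_cluster_with_all_reads_gives_one(self):
        clusters = [RepeatCluster("CL1", tuple(f"r{i}" for i in range(1000)), 1000)]
        est = repetitive_fraction(clusters, 1000)
        assert est.repetitive_fraction == 1.0
        assert est.qualifying_clusters == ["CL1"]

    def test_zero_sampled_reads_rejected(self):
        with pytest.raises(ValueError):
            repetitive_fraction([], 0)

    def test_tracers_do_not_count_toward_fraction(self):
        spec = SimFamilySpec("E", "gypsy", "A", 1000, 0)
        panel = simulate_reference_panel([spec], seed=0)
        from ltrtracer.tracers import kmerize_element

        kmers = kmerize_element(panel[0])
        reads = [("r0", panel[0].sequence[:100]), ("r1", panel[0].sequence[10:110])]
        clusters = cluster_sequences(reads, kmers, method="exact")
        est = repetitive_fraction(clusters, 2, min_size=1)
        # both reads join the tracer cluster; fraction counts reads only
        assert clusters[0].read_count == 2
        assert clusters[0].tracer_total == len(kmers)
        assert est.repetitive_fraction == 1.0


class TestReplicates:
    def test_identical_runs_have_zero_se(self):
        rng = np.random.default_rng(9)
        seqs = [
            SequenceRead(f"r{i}", s)
            for i, (_, s) in enumerate(_family_reads(rng, 30, divergence=0.01))
        ]
        with pytest.warns(UserWarning):
            result = replicate_fraction(
                seqs, n_runs=3, n_per_run=10_000, method="exact"
            )
        assert result.se == 0.0
        assert len(result.per_run) == 3
        assert result.mean == result.per_run[0].repetitive_fraction

    def test_mean_is_arithmetic_mean_of_runs(self):
        rng = np.random.default_rng(10)
        seqs = [
            SequenceRead(f"r{i}", s)
            for i, (_, s) in enumerate(_family_reads(rng, 80, divergence=0.02))
        ]
        result = replicate_fraction(seqs, n_runs=5, n_per_run=40, method="exact")
        values = [e.repetitive_fraction for e in result.per_run]
        assert len(values) == 5
        assert result.mean == pytest.approx(np.mean(values))
        assert result.se == pytest.approx(np.std(values, ddof=1) / math.sqrt(5))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            replicate_fraction([], n_runs=1)


def test_fraction_monotone_in_copy_number():
    """More TE copies -> higher estimated repetitive fraction."""
    fractions = []
    for copies in (10, 40, 160):
        spec = SimFamilySpec("F", "gypsy", "A", 1000, copies, 0.01, 0.0)
        panel = simulate_reference_panel([spec], seed=1)
        genome = simulate_species_genome(panel, [spec], 200_000, seed=2,
                                         min_spacing=300)
        reads = simulate_reads(genome, ReadSimConfig(n_reads=1000, seed=3))
        clusters = cluster_sequences(reads, method="components")
        est = repetitive_fraction(clusters, 1000, min_cluster_frac=0.01)
        fractions.append(est.repetitive_fraction)
    assert fractions[0] <= fractions[1] <= fractions[2]


def test_sequence_pool_rejects_duplicate_ids():
    with pytest.raises(ValueError):
        SequencePool([("a", "ACGT" * 25), ("a", "TTTT" * 25)])
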