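"""Span-position distance, clique clustering and cluster scoring."""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svclique.clustering import (
    build_graph,
    cluster_signatures,
    enumerate_maximal_cliques,
    partition_signatures,
    resolve_overlapping_cliques,
    score_cluster,
    span_position_distance,
)
from svclique.model import ClusterParams
from tests.conftest import make_sig


class TestSpanPositionDistance:
    def test_position_and_span_terms_exchange_at_n(self):
        """900 bp apart with equal spans costs exactly as much as
        co-located with maximally different spans (the role of N)."""
        shifted = span_position_distance(
            make_sig(begin=1000, end=1500), make_sig(begin=1900, end=2400), 900
        )
        assert shifted == pytest.approx(1.0)

    def test_hand_computed_mixed_case(self):
        # spans 100 vs 1000 -> SD 0.9; identical midpoints -> PD 0
        d = span_position_distance(
            make_sig(begin=1000, end=1100), make_sig(begin=550, end=1550), 900
        )
        assert d == pytest.approx(0.9)

    def test_identity(self):
        s = make_sig(begin=1000, end=1200)
        assert span_position_distance(s, s, 900) == 0.0

    def test_zero_span_pair_is_positional_only(self):
        b1 = make_sig("BRK", begin=1000, end=1000, evidence_class="inter",
                      mate=("chr2", 5))
        b2 = make_sig("BRK", begin=1450, end=1450, evidence_class="inter",
                      mate=("chr2", 5))
        assert span_position_distance(b1, b2, 900) == pytest.approx(0.5)

    @settings(max_examples=300, derandomize=True)
    @given(
        b1=st.integers(0, 10**6), l1=st.integers(1, 10**4),
        b2=st.integers(0, 10**6), l2=st.integers(1, 10**4),
    )
    def test_metric_sanity(self, b1, l1, b2, l2):
        s1 = make_sig(begin=b1, end=b1 + l1)
        s2 = make_sig(begin=b2, end=b2 + l2)
        d12 = span_position_distance(s1, s2, 900)
        assert d12 == span_position_distance(s2, s1, 900)
        assert d12 >= 0
        sd = d12 - min(abs(b1 - b2), abs(b1 + l1 - b2 - l2),
                       abs(s1.midpoint - s2.midpoint)) / 900
        assert 0 <= sd < 1


class TestGraph:
    def test_partition_by_type_and_chrom(self):
        sigs = [
            make_sig(chrom="chr1"), make_sig(chrom="chr2"),
            make_sig("INS", chrom="chr1"),
        ]
        buckets = partition_signatures(sigs)
        assert set(buckets) == {("DEL", "chr1"), ("DEL", "chr2"), ("INS", "chr1")}
        assert partition_signatures([]) == {}

    def test_edge_iff_distance_below_threshold(self):
        far = [make_sig(begin=1000, end=1500), make_sig(begin=1900, end=2400)]
        assert build_graph(far, ClusterParams()).number_of_edges() == 0  # SPD 1.0

        mixed = [make_sig(begin=1000, end=1100), make_sig(begin=550, end=1550)]
        assert build_graph(mixed, ClusterParams()).number_of_edges() == 0  # 0.9
        loose = ClusterParams(edge_threshold_t=0.95)
        assert build_graph(mixed, loose).number_of_edges() == 1

        twins = [make_sig(), make_sig(read_name="r2")]
        assert build_graph(twins, ClusterParams()).number_of_edges() == 1

    def test_pruning_does_not_change_graph(self):
        rnd = random.Random(3)
        sigs = [
            make_sig(begin=b, end=b + rnd.randint(50, 2000))
            for b in (rnd.randint(0, 50_000) for _ in range(60))
        ]
        bucket = sorted(sigs, key=lambda s: s.begin)
        params = ClusterParams()
        g1 = build_graph(bucket, params, prune=True)
        g2 = build_graph(bucket, params, prune=False)
        assert set(g1.edges) == set(g2.edges)


def brute_force_cliques(graph):
    """Independent oracle: test every vertex subset for maximal cliquehood."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                if not any(
                    all(graph.has_edge(v, u) for u in subset)
                    for v in nodes if v not in subset
                ):
                    cliques.append(frozenset(subset))
    return set(cliques)


class TestCliques:
    def test_triangle_and_path(self):
        tri = nx.complete_graph(3)
        assert enumerate_maximal_cliques(tri) == [{0, 1, 2}]
        path = nx.path_graph(3)
        assert enumerate_maximal_cliques(path) == [{0, 1}, {1, 2}]

    def test_isolated_vertices_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(0, 1)
        assert enumerate_maximal_cliques(g) == [{0, 1}, {2}]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(2, 12)
        g = nx.gnp_random_graph(n, rnd.uniform(0.2, 0.8), seed=seed)
        got = {frozenset(c) for c in enumerate_maximal_cliques(g)}
        assert got == brute_force_cliques(g)


class TestOverlapResolution:
    def test_disjoint_untouched(self):
        bucket = [make_sig(read_name=f"r{i}") for i in range(4)]
        cliques = [{0, 1}, {2, 3}]
        assert sorted(
            map(sorted, resolve_overlapping_cliques(cliques, bucket))
        ) == [[0, 1], [2, 3]]

    def test_larger_clique_wins_shared_vertex(self):
        bucket = [make_sig(read_name=f"r{i}") for i in range(4)]
        out = resolve_overlapping_cliques([{2, 3}, {0, 1, 2}], bucket)
        assert sorted(map(sorted, out)) == [[0, 1, 2], [3]]

    def test_duplicates_collapse(self):
        bucket = [make_sig(read_name=f"r{i}") for i in range(2)]
        out = resolve_overlapping_cliques([{0, 1}, {0, 1}], bucket)
        assert sorted(map(sorted, out)) == [[0, 1]]


def identical_members(n_intra, n_inter, **kw):
    members = [
        make_sig(read_name=f"i{k}", evidence_class="intra", **kw)
        for k in range(n_intra)
    ]
    members += [
        make_sig(read_name=f"j{k}", evidence_class="inter", **kw)
        for k in range(n_inter)
    ]
    return members


class TestScore:
    def test_saturated_perfect_cluster_reaches_100(self):
        sc = score_cluster(identical_members(20, 20))
        assert (sc.n, sc.b, sc.sp, sc.ss) == (40, 30, 10.0, 20.0)
        assert sc.total == 100.0

    def test_per_class_cap(self):
        sc = score_cluster(identical_members(35, 0))
        assert (sc.n, sc.b) == (20, 10)

    def test_mixed_small_cluster(self):
        sc = score_cluster(identical_members(3, 1))
        assert (sc.n, sc.b, sc.sp, sc.ss, sc.total) == (4, 30, 10.0, 20.0, 64.0)

    def test_dispersion_reduces_consistency_terms(self):
        spread = [
            make_sig(begin=1000 + 120 * k, end=1100 + 120 * k, read_name=f"r{k}")
            for k in range(4)
        ]
        sc = score_cluster(spread)
        assert sc.sp < 10 and sc.ss == 20.0  # same spans, scattered positions
        assert 0 < sc.total <= 100

    def test_all_breakend_cluster_zero_span_fallback(self):
        members = [
            make_sig("BRK", begin=500, end=500, evidence_class="inter",
                     read_name=f"r{k}", mate=("chr2", 9))
            for k in range(3)
        ]
        sc = score_cluster(members)
        assert (sc.sp, sc.ss) == (10.0, 20.0)

    def test_adding_identical_member_never_decreases_components(self):
        base = identical_members(2, 1)
        bigger = identical_members(3, 1)
        a, b = score_cluster(base), score_cluster(bigger)
        assert b.n >= a.n and b.b >= a.b and b.sp >= a.sp and b.ss >= a.ss

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            score_cluster([])


class TestClusterSignatures:
    def test_jittered_signatures_collapse_to_one_cluster(self):
        rnd = random.Random(0)
        sigs = [
            make_sig(begin=10_000 + rnd.randint(-5, 5),
                     end=10_400 + rnd.randint(-5, 5), read_name=f"r{k}")
            for k in range(6)
        ]
        (cluster,) = cluster_signatures(sigs)
        assert abs(cluster.begin - 10_000) <= 5
        assert abs(cluster.end - 10_400) <= 5
        assert len(cluster.members) == 6

    def test_distant_events_stay_separate(self):
        sigs = [
            make_sig(begin=b + 3 * k, end=b + 400 + 3 * k, read_name=f"r{b}_{k}")
            for b in (10_000, 60_000) for k in range(6)
        ]
        clusters = cluster_signatures(sigs)
        assert len(clusters) == 2
        assert [len(c.members) for c in clusters] == [6, 6]

    def test_empty_input(self):
        assert cluster_signatures([]) == []

    def test_dup_origin_consensus_is_median(self):
        sigs = [
            make_sig("DUP", begin=5000, end=5500, evidence_class="inter",
                     read_name=f"r{k}",
                     origin=("chr5", 100 + k, 600 + k))
            for k in range(3)
        ]
        (cluster,) = cluster_signatures(sigs)
        assert cluster.origin_consensus == ("chr5", 101, 601)
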