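"""The detector: ECC, node weights, cores, adhesion, attachments, filtering."""

import io
import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dca import (
    Complex,
    DetectionParams,
    ExpressionProfileSet,
    SyntheticConfig,
    adhesion,
    attach,
    build_dynamic_network,
    build_weighted_snapshot,
    detect,
    edge_clustering_coefficient,
    filter_redundancy,
    generate_benchmark,
    node_weight,
    overlap_score,
    seed_cores,
    write_complex_set,
)
from conftest import graph_from_edges


def ecc_brute_force(graph, i, j):
    """Independent oracle: enumerate triangles through the edge."""
    triangles = sum(
        1
        for w in graph.nodes
        if w not in (i, j) and graph.has_edge(i, w) and graph.has_edge(j, w)
    )
    denom = min(graph.degree(i), graph.degree(j)) - 1
    return 0.0 if denom <= 0 else triangles / denom


def random_graph(seed, n_max=30, p=0.25):
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


class TestECC:
    def test_triangle_edge(self, triangle):
        for e in triangle.edges:
            assert edge_clustering_coefficient(triangle, *e) == pytest.approx(1.0)

    def test_path_edge_degenerate_denominator(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        assert edge_clustering_coefficient(g, "a", "b") == 0.0

    def test_half_shared_neighborhood(self):
        g = graph_from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "e")]
        )
        # Z=1 (c), k_a=k_b=3 -> 1/2
        assert edge_clustering_coefficient(g, "a", "b") == pytest.approx(0.5)

    def test_missing_edge_errors(self, triangle):
        with pytest.raises(ValueError):
            edge_clustering_coefficient(triangle, "A", "Z")

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_triangle_enumeration_oracle(self, seed):
        g = random_graph(seed)
        for u, v in g.edges:
            got = edge_clustering_coefficient(g, u, v)
            assert got == pytest.approx(ecc_brute_force(g, u, v))
            assert 0.0 <= got <= 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_removing_non_common_neighbor_preserves_ecc(self, seed):
        g = random_graph(seed, n_max=15, p=0.35)
        rng = random.Random(seed)
        edges = list(g.edges)
        if not edges:
            return
        u, v = rng.choice(edges)
        common = set(g.adj[u]) & set(g.adj[v])
        outsiders = set(g.nodes) - common - {u, v} - set(g.adj[u]) - set(g.adj[v])
        before = edge_clustering_coefficient(g, u, v)
        for w in outsiders:
            g2 = g.copy()
            g2.remove_node(w)
            assert edge_clustering_coefficient(g2, u, v) == pytest.approx(before)


class TestNodeWeight:
    def test_triangle_node(self, triangle):
        ws = build_weighted_snapshot(triangle, {g: 1.0 for g in "ABC"}, alpha=0.6)
        # ECC sum = 2, AT = 1 -> 0.6*2 + 0.4*1 = 1.6
        assert ws.weight["A"] == pytest.approx(1.6)

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("X")
        w = node_weight(g, {}, "X", at_norm=0.5, alpha=0.6)
        assert w == pytest.approx(0.2)

    def test_alpha_boundary_identities(self, triangle):
        at = {"A": 0.3, "B": 0.7, "C": 0.9}
        ws1 = build_weighted_snapshot(triangle, at, alpha=1.0)
        ws0 = build_weighted_snapshot(triangle, at, alpha=0.0)
        for v in triangle.nodes:
            ecc_sum = sum(ws1.edge_ecc(v, u) for u in triangle.adj[v])
            assert ws1.weight[v] == pytest.approx(ecc_sum)
            assert ws0.weight[v] == pytest.approx(at[v])


class TestSeedCores:
    def test_triangle_yields_single_core(self, triangle):
        ws = build_weighted_snapshot(triangle, {g: 1.0 for g in "ABC"}, alpha=0.6)
        cores = seed_cores(ws, beta=0.55)
        assert cores == [frozenset({"A", "B", "C"})]

    def test_single_edge_cannot_seed(self):
        g = graph_from_edges([("A", "B")])
        ws = build_weighted_snapshot(g, {"A": 1.0, "B": 1.0}, alpha=0.6)
        # degree-1 nodes have zero ECC sum: weight <= 0.4 < beta
        assert seed_cores(ws, beta=0.55) == []

    def test_empty_graph(self):
        ws = build_weighted_snapshot(nx.Graph(), {}, alpha=0.6)
        assert seed_cores(ws, beta=0.55) == []

    def test_strict_comparison(self, triangle):
        ws = build_weighted_snapshot(triangle, {g: 1.0 for g in "ABC"}, alpha=0.6)
        assert seed_cores(ws, beta=1.6) == []  # weight == beta does not seed

    @given(seed=st.integers(0, 10_000), b1=st.floats(0, 3), b2=st.floats(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_core_count_non_increasing_in_beta(self, seed, b1, b2):
        b1, b2 = sorted((b1, b2))
        g = random_graph(seed, n_max=15, p=0.3)
        at = {v: random.Random(seed + 1).random() for v in g.nodes}
        ws = build_weighted_snapshot(g, at, alpha=0.6)
        assert len(seed_cores(ws, b2)) <= len(seed_cores(ws, b1))


def _star_core_snapshot():
    """Triangle core {a,b,c} plus s-(a,b) and a pendant t-a."""
    g = graph_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("s", "a"), ("s", "b"), ("t", "a")]
    )
    at = {v: 1.0 for v in g.nodes}
    return build_weighted_snapshot(g, at, alpha=0.6)


class TestAdhesionAndAttach:
    def test_worked_adhesion(self):
        ws = _star_core_snapshot()
        core = frozenset({"a", "b", "c"})
        # ECC(s,a) = ECC(s,b) = 1 -> Adh = 2
        assert adhesion(ws, core, "s") == pytest.approx(2.0)

    def test_zero_ecc_single_edge_adhesion(self):
        ws = _star_core_snapshot()
        assert adhesion(ws, frozenset({"a", "b", "c"}), "t") == 0.0

    def test_non_neighbor_has_zero_adhesion(self):
        g = graph_from_edges([("a", "b"), ("x", "y")])
        ws = build_weighted_snapshot(g, {}, alpha=0.6)
        assert adhesion(ws, frozenset({"a", "b"}), "x") == 0.0

    def test_core_member_errors(self):
        ws = _star_core_snapshot()
        with pytest.raises(ValueError):
            adhesion(ws, frozenset({"a", "b"}), "a")

    def test_absolute_attachment_selection(self):
        ws = _star_core_snapshot()
        cx = attach(ws, frozenset({"a", "b", "c"}), gamma=1.4)
        assert cx.attachments == frozenset({"s"})  # t has Adh 0

    def test_gamma_zero_attaches_everyone(self):
        ws = _star_core_snapshot()
        cx = attach(ws, frozenset({"a", "b", "c"}), gamma=0.0)
        assert cx.attachments == frozenset({"s", "t"})

    def test_score_is_summed_weight(self):
        ws = _star_core_snapshot()
        cx = attach(ws, frozenset({"a", "b", "c"}), gamma=1.4)
        expect = sum(ws.weight[v] for v in {"a", "b", "c", "s"})
        assert cx.score == pytest.approx(expect)

    def test_relative_mode(self):
        ws = _star_core_snapshot()
        # candidate adhesions: s=2, t=0; mean=1; gamma=1.5 -> cutoff 1.5
        cx = attach(ws, frozenset({"a", "b", "c"}), gamma=1.5, mode="relative")
        assert cx.attachments == frozenset({"s"})

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_attach_order_independent(self, seed):
        """The attachment set equals an explicit per-candidate sweep in
        any candidate order."""
        g = random_graph(seed, n_max=14, p=0.35)
        rng = random.Random(seed)
        at = {v: rng.random() for v in g.nodes}
        ws = build_weighted_snapshot(g, at, alpha=0.6)
        nodes = sorted(g.nodes)
        if len(nodes) < 3:
            return
        core = frozenset(rng.sample(nodes, k=min(3, len(nodes))))
        cx = attach(ws, core, gamma=0.8)
        candidates = list({u for v in core for u in g.adj[v]} - set(core))
        rng.shuffle(candidates)
        manual = {s for s in candidates if adhesion(ws, core, s) >= 0.8}
        assert cx.attachments == frozenset(manual)

    @given(seed=st.integers(0, 10_000), g1=st.floats(0, 4), g2=st.floats(0, 4))
    @settings(max_examples=30, deadline=None)
    def test_attachments_non_increasing_in_gamma(self, seed, g1, g2):
        g1, g2 = sorted((g1, g2))
        graph = random_graph(seed, n_max=14, p=0.35)
        rng = random.Random(seed)
        at = {v: rng.random() for v in graph.nodes}
        ws = build_weighted_snapshot(graph, at, alpha=0.6)
        nodes = sorted(graph.nodes)
        if len(nodes) < 3:
            return
        core = frozenset(rng.sample(nodes, k=3))
        lo = attach(ws, core, gamma=g1).attachments
        hi = attach(ws, core, gamma=g2).attachments
        assert hi <= lo


def _cx(cid, members, score):
    return Complex(id=cid, core=frozenset(members), score=score)


class TestFilterRedundancy:
    def test_identical_complexes_collapse(self):
        a = _cx("A", "abc", 2.0)
        b = _cx("B", "abc", 1.0)
        kept = filter_redundancy([a, b], 0.8)
        assert len(kept) == 1 and kept[0].id == "A"

    def test_disjoint_complexes_both_kept(self):
        kept = filter_redundancy([_cx("A", "abc", 2.0), _cx("B", "xyz", 1.0)], 0.8)
        assert len(kept) == 2

    def test_near_duplicate_dropped_at_threshold(self):
        big = _cx("A", "abcdefghij", 5.0)          # {a..j}
        near = _cx("B", "abcdefghik", 4.0)         # {a..i, k}, OS = 81/100
        assert overlap_score(big.members, near.members) == pytest.approx(0.81)
        kept = filter_redundancy([near, big], 0.8)
        assert [c.id for c in kept] == ["A"]

    def test_output_has_no_redundant_pair(self):
        rng = random.Random(7)
        pool = "abcdefghijklmnop"
        cxs = [
            _cx(f"C{i}", rng.sample(pool, k=rng.randint(3, 8)), rng.random())
            for i in range(40)
        ]
        kept = filter_redundancy(cxs, 0.8)
        sets = [c.members for c in kept]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert overlap_score(sets[i], sets[j]) < 0.8


class TestDetect:
    def test_all_inactive_expression_yields_nothing(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        prof = ExpressionProfileSet(
            {g_: np.full(6, 5.0) for g_ in "ABC"}, 6
        )
        dyn = build_dynamic_network(g, prof)
        assert len(detect(dyn)) == 0

    def test_deterministic_serialized_output(self, benchmark):
        net, prof, _ = benchmark

        def run():
            dyn = build_dynamic_network(net, prof)
            buf = io.StringIO()
            write_complex_set(detect(dyn), buf)
            return buf.getvalue()

        assert run() == run()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(alpha=1.5).validate()
        with pytest.raises(ValueError):
            DetectionParams(redundancy_threshold=0.0).validate()
        with pytest.raises(ValueError):
            DetectionParams(adhesion_mode="sometimes").validate()

    def test_min_size_respected(self, benchmark):
        net, prof, _ = benchmark
        dyn = build_dynamic_network(net, prof)
        preds = detect(dyn, DetectionParams(min_complex_size=4))
        assert all(len(c) >= 4 for c in preds)

    def test_members_are_snapshot_nodes(self, benchmark):
        net, prof, _ = benchmark
        dyn = build_dynamic_network(net, prof)
        for cx in detect(dyn):
            snap = dyn.snapshots[cx.time_point - 1]
            assert cx.members <= set(snap.nodes)
            assert cx.core.isdisjoint(cx.attachments)
            assert len(cx.core) >= 2
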