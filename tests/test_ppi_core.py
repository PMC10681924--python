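"""Graph construction, the four centralities against oracles, and
median-filter core extraction."""

import networkx as nx
import numpy as np
import pytest

from conftest import brute_betweenness, brute_closeness, brute_degree, brute_eigenvector, random_graph
from netpharm.ppi_core import (
    PpiEdge,
    ValidationError,
    betweenness,
    build_graph,
    centrality_table,
    closeness,
    degree,
    eigenvector,
    extract_core,
    load_edge_list,
    median_filter_round,
)


def graph_of(*edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestBuildGraph:
    def test_inclusive_score_cutoff(self):
        edges = [PpiEdge("A", "B", 0.85), PpiEdge("B", "C", 0.90), PpiEdge("C", "D", 0.95)]
        g = build_graph(edges, 0.90)
        assert g.number_of_edges() == 2
        assert not g.has_edge("A", "B")

    def test_duplicate_pair_keeps_max_score(self):
        g = build_graph([PpiEdge("A", "B", 0.91), PpiEdge("B", "A", 0.99)], 0.9)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["score"] == 0.99

    def test_self_loop_dropped_and_no_isolated_endpoints(self):
        g = build_graph([PpiEdge("A", "A", 1.0), PpiEdge("B", "C", 0.5)], 0.9)
        assert g.number_of_nodes() == 0

    def test_score_validation(self):
        with pytest.raises(ValidationError):
            PpiEdge("A", "B", 1.5)
        with pytest.raises(ValidationError):
            build_graph([], min_score=2.0)

    def test_load_edge_list_two_column_defaults_score_one(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tC\t0.5\n")
        g = load_edge_list(p, 0.9)
        assert set(g.edges) == {("A", "B")}


class TestCentralityExamples:
    def test_path_degrees(self):
        g = graph_of(("A", "B"), ("B", "C"))
        assert degree(g) == {"A": 1, "B": 2, "C": 1}

    def test_complete_graph_degrees_and_handshake(self):
        g = nx.complete_graph(5)
        d = degree(g)
        assert all(v == 4 for v in d.values())
        assert sum(d.values()) == 2 * g.number_of_edges()

    def test_path_betweenness(self):
        g = graph_of(("A", "B"), ("B", "C"))
        bc = betweenness(g)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_betweenness_is_pair_count(self):
        g = graph_of(*(("X", f"L{i}") for i in range(4)))
        assert betweenness(g)["X"] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_star_closeness_center(self):
        g = graph_of(*(("X", f"L{i}") for i in range(4)))
        assert closeness(g)["X"] == pytest.approx(1.0)

    def test_path_endpoint_closeness(self):
        g = graph_of(("A", "B"), ("B", "C"))
        assert closeness(g)["A"] == pytest.approx(2 / 3)

    def test_disjoint_triangles_closeness_componentwise(self):
        g = graph_of(("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X"))
        assert all(v == pytest.approx(1.0) for v in closeness(g).values())

    def test_complete_graph_eigenvector_symmetry(self):
        g = nx.complete_graph(4)
        assert all(v == pytest.approx(1.0) for v in eigenvector(g).values())

    def test_star_eigenvector(self):
        g = graph_of(*(("X", f"L{i}") for i in range(4)))
        ec = eigenvector(g)
        assert ec["X"] == pytest.approx(1.0)
        for i in range(4):
            assert ec[f"L{i}"] == pytest.approx(0.5, abs=1e-8)

    def test_eigenvector_outside_largest_component_is_zero(self):
        g = graph_of(("A", "B"), ("B", "C"), ("X", "Y"))
        ec = eigenvector(g)
        assert ec["X"] == 0.0 and ec["Y"] == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            eigenvector(nx.Graph())


class TestCentralityOracles:
    def test_random_graphs_match_all_oracles(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            g = random_graph(rng, n_max=8)
            assert degree(g) == pytest.approx(brute_degree(g))
            assert betweenness(g) == pytest.approx(brute_betweenness(g), abs=1e-9)
            assert closeness(g) == pytest.approx(brute_closeness(g), abs=1e-9)
            ec, brute = eigenvector(g), brute_eigenvector(g)
            assert ec == pytest.approx(brute, abs=1e-6)

    def test_matches_networkx_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            g = random_graph(rng, n_max=10)
            assert betweenness(g) == pytest.approx(nx.betweenness_centrality(g, normalized=False), abs=1e-9)
            assert closeness(g) == pytest.approx(nx.closeness_centrality(g, wf_improved=False), abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        g = random_graph(rng, n_max=8)
        perm = {v: f"Z{i}" for i, v in enumerate(sorted(g.nodes))}
        h = nx.relabel_nodes(g, perm)
        for metric in (degree, betweenness, closeness, eigenvector):
            orig = metric(g)
            relabelled = metric(h)
            assert relabelled == pytest.approx({perm[v]: x for v, x in orig.items()}, abs=1e-8)

    def test_adding_edge_never_decreases_endpoint_degree(self):
        g = graph_of(("A", "B"), ("B", "C"))
        before = degree(g)
        g.add_edge("A", "C")
        after = degree(g)
        assert after["A"] >= before["A"] and after["C"] >= before["C"]


class TestMedianFilter:
    def test_four_node_path_degree_median(self):
        g = graph_of(("A", "B"), ("B", "C"), ("C", "D"))
        sub, medians = median_filter_round(g, metrics=["dc"])
        assert set(sub.nodes) == {"B", "C"}
        assert medians["dc"] == 1.5

    def test_all_ties_give_empty_result(self):
        g = nx.complete_graph(4)
        sub, _ = median_filter_round(g)
        assert sub.number_of_nodes() == 0

    def test_empty_graph_passes_through(self):
        sub, medians = median_filter_round(nx.Graph())
        assert sub.number_of_nodes() == 0 and medians == {}

    def test_never_increases_node_count(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            g = random_graph(rng)
            sub, _ = median_filter_round(g)
            assert sub.number_of_nodes() <= g.number_of_nodes()

    def test_matches_bruteforce_rule_on_planted_core(self):
        from netpharm.synthetic_data import SyntheticConfig, gen_ppi

        cfg = SyntheticConfig(seed=5)
        gen_ppi(cfg, "/tmp/_ppi_test.tsv")
        g = load_edge_list("/tmp/_ppi_test.tsv", 0.9)
        tables = centrality_table(g)
        medians = {m: float(np.median(list(tables[m].values()))) for m in tables}
        expected = {v for v in g if all(tables[m][v] > medians[m] for m in tables)}
        sub, _ = median_filter_round(g)
        assert set(sub.nodes) == expected


class TestExtractCore:
    def test_single_round_equals_one_filter(self):
        g = graph_of(("A", "B"), ("B", "C"), ("C", "D"))
        res = extract_core(g, metrics=["dc"], rounds=1)
        sub, _ = median_filter_round(g, metrics=["dc"])
        assert set(res.core_nodes) == set(sub.nodes)
        assert not res.exhausted

    def test_two_rounds_equal_manual_composition(self):
        rng = np.random.default_rng(15)
        g = random_graph(rng, n_max=8)
        while g.number_of_nodes() < 6:
            g = random_graph(rng, n_max=8)
        res = extract_core(g, rounds=2, mode="all")
        g1, _ = median_filter_round(g, mode="all")
        g2, _ = median_filter_round(g1, mode="all")
        survivors = g2 if g2.number_of_nodes() else (g1 if g1.number_of_nodes() else g)
        assert set(res.core_nodes) == set(survivors.nodes)

    def test_excess_rounds_stop_early_with_flag(self):
        g = nx.complete_graph(4)  # every metric ties, first round would empty
        res = extract_core(g, rounds=3, mode="all")
        assert res.exhausted
        assert set(res.core_nodes) == set(g.nodes)  # last non-empty graph

    def test_deterministic_ordered_output(self):
        rng = np.random.default_rng(16)
        g = random_graph(rng, n_max=8)
        a = extract_core(g)
        b = extract_core(g)
        assert a.core_nodes == b.core_nodes
        assert a.rounds == b.rounds

    def test_round_trace_counts_strictly_decrease(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            g = random_graph(rng, n_max=8)
            res = extract_core(g, rounds=3)
            counts = [g.number_of_nodes()] + [r["nodes"] for r in res.rounds]
            assert all(b < a for a, b in zip(counts, counts[1:]))
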