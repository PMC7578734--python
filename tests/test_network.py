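"""Co-usage network: construction, path statistics, k-core, layout, export."""

from collections import deque

import networkx as nx
import pytest

from acumine import (
    build_network,
    core_decomposition,
    export_graph,
    fr_layout,
    from_itemsets,
    graph_stats,
    k_core,
)
from acumine.network import read_exported_graph


# ---------------------------------------------------------------- oracles

def bfs_all_pairs(graph):
    """Independent all-pairs shortest-path lengths by explicit BFS."""
    dist = {}
    for source in graph.nodes:
        seen = {source: 0}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        dist[source] = seen
    return dist


def naive_k_core_members(graph, k):
    """Fixed-point peeling recomputing degrees from scratch each pass."""
    nodes = set(graph.nodes)
    while True:
        sub = graph.subgraph(nodes)
        drop = {n for n in nodes if sub.degree(n) < k}
        if not drop:
            return nodes
        nodes = nodes - drop


def random_graph(n, p, seed):
    return nx.gnp_random_graph(n, p, seed=seed)


# ------------------------------------------------------------ construction

class TestBuildNetwork:
    def test_csap_lu9_pc6_edge_weight(self, csap):
        graph = build_network(csap)
        assert graph["LU9"]["PC6"]["weight"] == 15

    def test_min_weight_filters_edges(self, csap):
        graph = build_network(csap, min_weight=16)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == len(csap.universe)

    def test_triangle_from_single_prescription(self):
        ds = from_itemsets({"S1": ["A1", "B1", "C1"]})
        graph = build_network(ds)
        assert sorted(graph.edges) == [("A1", "B1"), ("A1", "C1"), ("B1", "C1")]
        assert all(d["weight"] == 1 for _, _, d in graph.edges(data=True))

    def test_no_self_loops_and_degree_sum(self, csap):
        graph = build_network(csap)
        assert not list(nx.selfloop_edges(graph))
        assert sum(dict(graph.degree).values()) == 2 * graph.number_of_edges()

    def test_pc6_has_maximum_degree(self, csap):
        graph = build_network(csap)
        degrees = dict(graph.degree)
        assert degrees["PC6"] == max(degrees.values())

    def test_csap_diameter_small(self, csap):
        stats = graph_stats(build_network(csap))
        assert stats.diameter <= 3


# ------------------------------------------------------------- statistics

class TestGraphStats:
    def test_complete_graph_closed_form(self):
        stats = graph_stats(nx.complete_graph(4))
        assert stats.average_degree == 3
        assert stats.average_path_length == 1
        assert stats.diameter == 1

    def test_path_graph_closed_form(self):
        stats = graph_stats(nx.path_graph(3))
        assert stats.average_degree == pytest.approx(4 / 3)
        assert stats.average_path_length == pytest.approx(4 / 3)
        assert stats.diameter == 2

    def test_single_node_undefined_paths(self):
        graph = nx.Graph()
        graph.add_node("A1")
        stats = graph_stats(graph)
        assert stats.average_path_length is None
        assert stats.diameter is None

    def test_disconnected_uses_largest_component(self):
        graph = nx.Graph([("A", "B"), ("B", "C"), ("D", "E")])
        stats = graph_stats(graph)
        assert not stats.connected
        assert stats.component_size == 3
        assert stats.diameter == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle(self, seed):
        graph = random_graph(25, 0.15, seed)
        largest = graph.subgraph(
            max(nx.connected_components(graph), key=len)
        )
        dist = bfs_all_pairs(largest)
        pairs = [
            d for u, row in dist.items() for v, d in row.items() if u != v
        ]
        stats = graph_stats(graph)
        if largest.number_of_nodes() > 1:
            assert stats.average_path_length == pytest.approx(
                sum(pairs) / len(pairs)
            )
            assert stats.diameter == max(pairs)


# ----------------------------------------------------------------- k-core

class TestKCore:
    def test_triangle_with_pendant(self):
        graph = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert k_core(graph, 2).member_nodes == {"A", "B", "C"}

    def test_nesting(self, csap):
        graph = build_network(csap)
        decomposition = core_decomposition(graph)
        for k in range(decomposition.k + 1):
            assert k_core(graph, k + 1).member_nodes <= k_core(graph, k).member_nodes

    def test_members_have_internal_degree_k(self, csap):
        graph = build_network(csap)
        for k in (2, 5, core_decomposition(graph).k):
            members = k_core(graph, k).member_nodes
            sub = graph.subgraph(members)
            assert all(sub.degree(n) >= k for n in members)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_fixed_point_oracle(self, seed):
        graph = random_graph(30, 0.2, seed)
        decomposition = core_decomposition(graph)
        for k in range(decomposition.k + 2):
            assert k_core(graph, k).member_nodes == naive_k_core_members(graph, k)

    def test_core_numbers_consistent_with_membership(self, csap):
        graph = build_network(csap)
        decomposition = core_decomposition(graph)
        for k in range(decomposition.k + 1):
            expected = {n for n, c in decomposition.core_number.items() if c >= k}
            assert k_core(graph, k).member_nodes == expected


# ----------------------------------------------------------------- layout

class TestLayout:
    def test_fixed_seed_is_bitwise_deterministic(self, csap):
        graph = build_network(csap)
        a = fr_layout(graph, iterations=30, seed=7)
        b = fr_layout(graph, iterations=30, seed=7)
        assert a == b

    def test_different_seeds_differ(self, csap):
        graph = build_network(csap)
        assert fr_layout(graph, seed=1) != fr_layout(graph, seed=2)

    def test_coordinates_bounded_by_frame(self, csap):
        graph = build_network(csap)
        layout = fr_layout(graph, area=4.0, seed=3)
        scale = 2.0 + 1e-9
        assert all(abs(x) <= scale and abs(y) <= scale
                   for x, y in layout.values())

    def test_star_hub_nearer_leaf_centroid_than_any_leaf(self):
        graph = nx.star_graph(8)
        layout = fr_layout(graph, iterations=100, seed=5)
        leaves = [n for n in graph.nodes if n != 0]
        cx = sum(layout[n][0] for n in leaves) / len(leaves)
        cy = sum(layout[n][1] for n in leaves) / len(leaves)

        def dist(node):
            x, y = layout[node]
            return ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5

        assert dist(0) < min(dist(n) for n in leaves)


# ----------------------------------------------------------------- export

class TestExport:
    def test_triangle_row_counts(self, tmp_path):
        graph = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        nodes, edges = tmp_path / "n.csv", tmp_path / "e.csv"
        export_graph(graph, fr_layout(graph, seed=1), nodes, edges)
        assert len(nodes.read_text().splitlines()) == 4
        assert len(edges.read_text().splitlines()) == 4

    def test_round_trip_isomorphic(self, csap, tmp_path):
        graph = build_network(csap)
        nodes, edges = tmp_path / "n.csv", tmp_path / "e.csv"
        export_graph(graph, None, nodes, edges)
        again = read_exported_graph(nodes, edges)
        assert set(again.nodes) == set(graph.nodes)
        assert {frozenset(e) for e in again.edges} == {
            frozenset(e) for e in graph.edges
        }
        for u, v, d in graph.edges(data=True):
            assert again[u][v]["weight"] == d["weight"]

    def test_first_node_row_is_max_degree(self, csap, tmp_path):
        graph = build_network(csap)
        nodes, edges = tmp_path / "n.csv", tmp_path / "e.csv"
        export_graph(graph, None, nodes, edges)
        first = nodes.read_text().splitlines()[1].split(",")
        assert first[1] == "PC6"
        assert int(first[2]) == max(dict(graph.degree).values())
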