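"""Weighted co-usage network of acupoints.

Two acupoints are linked when they appear together in at least
``min_weight`` prescriptions; the edge weight is the raw co-occurrence
count.  Although association-rule flows are sometimes described as
directed, joint usage is symmetric, so the graph here is undirected and
"degree" means the single undirected degree.  Path statistics use
unweighted breadth-first shortest paths on the largest connected
component; core acupoints are extracted by k-core peeling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .cooccurrence import cooccurrence_matrix
from .registry import TransactionDataset


@dataclass
class GraphStats:
    """Global statistics of a co-usage graph.

    Path statistics (``average_path_length``, ``diameter``) are computed on
    the largest connected component; ``component_size`` records how many
    nodes that component has and ``connected`` whether it was the whole
    graph.  For a single-node graph both path statistics are ``None``.
    """

    node_count: int
    edge_count: int
    average_degree: float
    average_path_length: float | None
    diameter: int | None
    connected: bool
    component_size: int
    path_convention: str = "unweighted BFS on largest connected component"


@dataclass
class KCoreResult:
    """k-core membership and full core numbers from iterative peeling."""

    k: int
    member_nodes: set[str]
    core_number: dict[str, int] = field(default_factory=dict)


def build_network(dataset: TransactionDataset, min_weight: int = 1) -> nx.Graph:
    """Undirected co-usage graph: edge (a, b) iff the pair co-occurs in at
    least ``min_weight`` prescriptions, weighted by the co-occurrence count.

    Nodes are all universe acupoints, including any left isolated by the
    weight threshold.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    matrix = cooccurrence_matrix(dataset)
    graph = nx.Graph()
    graph.add_nodes_from(dataset.universe)
    items = matrix.items
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            w = matrix.count(items[i], items[j])
            if w >= min_weight:
                graph.add_edge(items[i], items[j], weight=w)
    return graph


def graph_stats(graph: nx.Graph) -> GraphStats:
    """Node/edge counts, average degree 2E/V, and BFS path statistics on
    the largest connected component."""
    V = graph.number_of_nodes()
    if V == 0:
        raise ValueError("empty graph")
    E = graph.number_of_edges()
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    largest = graph.subgraph(components[0])
    if largest.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(largest)
        diam = nx.diameter(largest)
    else:
        apl = None
        diam = None
    return GraphStats(
        node_count=V,
        edge_count=E,
        average_degree=2 * E / V,
        average_path_length=apl,
        diameter=diam,
        connected=len(components) == 1,
        component_size=largest.number_of_nodes(),
    )


def core_decomposition(graph: nx.Graph) -> KCoreResult:
    """Full core numbers by iterative peeling; ``k`` is the graph's
    degeneracy (the largest k with a non-empty k-core)."""
    core = nx.core_number(graph) if graph.number_of_nodes() else {}
    k_max = max(core.values(), default=0)
    members = {n for n, c in core.items() if c >= k_max}
    return KCoreResult(k=k_max, member_nodes=members, core_number=dict(core))


def k_core(graph: nx.Graph, k: int) -> KCoreResult:
    """Members surviving k-core peeling: repeatedly remove nodes whose
    degree within the remaining subgraph is below k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    core = nx.core_number(graph) if graph.number_of_nodes() else {}
    members = {n for n, c in core.items() if c >= k}
    return KCoreResult(k=k, member_nodes=members, core_number=dict(core))


def fr_layout(
    graph: nx.Graph,
    iterations: int = 50,
    area: float = 1.0,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold force-directed layout.

    Attractive forces act along edges and repulsive forces between all
    node pairs, with a cooling temperature schedule; the seed fixes the
    initial placement, so equal seeds give identical coordinates.
    Coordinates are scaled to the square frame [-scale, scale] with
    scale = sqrt(area).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    scale = area ** 0.5
    pos = nx.spring_layout(
        graph, iterations=iterations, seed=seed, scale=scale, center=(0.0, 0.0)
    )
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}


def export_graph(
    graph: nx.Graph,
    layout: dict[str, tuple[float, float]] | None,
    node_path: str | Path,
    edge_path: str | Path,
) -> None:
    """Write Gephi-style node and edge lists as delimited text.

    Node rows carry id, code, degree, core number and layout coordinates;
    edge rows carry source, target, weight.  Rows are ordered by
    descending degree then code, and source < target lexicographically,
    so repeated exports are byte-identical.
    """
    core = nx.core_number(graph) if graph.number_of_nodes() else {}
    nodes = sorted(graph.nodes, key=lambda n: (-graph.degree(n), n))
    with open(node_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "code", "degree", "core_number", "x", "y"])
        for idx, node in enumerate(nodes, start=1):
            x, y = (layout or {}).get(node, ("", ""))
            writer.writerow([idx, node, graph.degree(node), core.get(node, 0), x, y])
    edges = sorted(
        (tuple(sorted((u, v))) + (d.get("weight", 1),))
        for u, v, d in graph.edges(data=True)
    )
    with open(edge_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        writer.writerows(edges)


def read_exported_graph(node_path: str | Path, edge_path: str | Path) -> nx.Graph:
    """Rebuild a graph from exported node/edge lists (round-trip helper)."""
    graph = nx.Graph()
    with open(node_path, newline="") as fh:
        for row in csv.DictReader(fh):
            graph.add_node(row["code"])
    with open(edge_path, newline="") as fh:
        for row in csv.DictReader(fh):
            graph.add_edge(row["source"], row["target"], weight=int(row["weight"]))
    return graph
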