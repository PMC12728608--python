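"""Graph metrics for water networks.

Seven quantities summarise a network: graph density, degree-distribution
(Shannon) entropy, characteristic path length averaged over connected
components, characteristic path length of the largest component, the number
of connected components, per-node clustering coefficients, and shortest paths
between chosen atoms.  Except for density on directed graphs, all metrics are
computed on the undirected projection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import WaterNetwork

__all__ = [
    "NetworkMetrics",
    "graph_density",
    "graph_entropy",
    "characteristic_path_length",
    "connected_components",
    "clustering_coefficient",
    "shortest_path",
    "compute_metrics",
]


@dataclass
class NetworkMetrics:
    """Scalar metrics of one network plus the per-node clustering map."""

    structure_id: str
    frame_index: int | None
    n_nodes: int
    n_edges: int
    density: float
    entropy: float                      # nats; 0 for regular graphs
    cpl_mean: float | None              # mean CPL over components with >= 2 nodes
    cpl_largest: float | None           # CPL of the largest component
    n_components: int
    clustering_coefficients: dict[int, float]
    n_ww_interactions: int
    n_wp_interactions: int


def _as_graph(net: WaterNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, WaterNetwork) else net


def _undirected(g: nx.Graph) -> nx.Graph:
    return g.to_undirected(as_view=False) if g.is_directed() else g


def graph_density(net: WaterNetwork | nx.Graph) -> float:
    """Edges over possible edges: 2E/(N(N−1)) undirected, E/(N(N−1)) directed.

    Graphs with fewer than two nodes have density 0 by convention.
    """
    g = _as_graph(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        return 0.0
    possible = n * (n - 1) if g.is_directed() else n * (n - 1) / 2
    return e / possible


def graph_entropy(net: WaterNetwork | nx.Graph) -> float:
    """Shannon entropy (nats) of the empirical node-degree distribution.

    A graph where every node has the same degree (a regular graph, including
    the empty graph) is perfectly ordered and scores 0; broader degree
    distributions score higher.
    """
    g = _undirected(_as_graph(net))
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    counts = Counter(d for _, d in g.degree())
    probs = np.array(list(counts.values()), dtype=float) / n
    return float(-np.sum(probs * np.log(probs)))


def _component_cpl(g: nx.Graph, nodes: set) -> float:
    sub = g.subgraph(nodes)
    return nx.average_shortest_path_length(sub)


def characteristic_path_length(net: WaterNetwork | nx.Graph,
                               ) -> tuple[float | None, float | None]:
    """(mean CPL over components, CPL of the largest component).

    Each component's CPL is the mean shortest-path edge count over its vertex
    pairs; singleton components contribute no pairs and are excluded from the
    average.  The largest component is the one with the most nodes (ties:
    more edges, then the one containing the smallest node key).  Both values
    are None when no component has two or more nodes.
    """
    g = _undirected(_as_graph(net))
    comps = [set(c) for c in nx.connected_components(g)]
    sized = [c for c in comps if len(c) >= 2]
    if not sized:
        return None, None
    cpls = [_component_cpl(g, c) for c in sized]
    cpl_mean = float(np.mean(cpls))
    largest = min(
        range(len(sized)),
        key=lambda i: (-len(sized[i]), -g.subgraph(sized[i]).number_of_edges(),
                       min(sized[i])))
    return cpl_mean, float(cpls[largest])


def connected_components(net: WaterNetwork | nx.Graph) -> int:
    g = _undirected(_as_graph(net))
    return nx.number_connected_components(g)


def clustering_coefficient(net: WaterNetwork | nx.Graph) -> dict:
    """Per-node local clustering coefficient (undirected projection)."""
    g = _undirected(_as_graph(net))
    return dict(nx.clustering(g))


def shortest_path(net: WaterNetwork | nx.Graph, a, b) -> list | None:
    """One minimum-hop path from *a* to *b*; None when disconnected."""
    g = _undirected(_as_graph(net))
    if a not in g or b not in g:
        raise KeyError(f"node not in graph: {a if a not in g else b}")
    try:
        return nx.shortest_path(g, a, b)
    except nx.NetworkXNoPath:
        return None


def compute_metrics(net: WaterNetwork) -> NetworkMetrics:
    """All scalar metrics of one network in a single record."""
    g = net.graph
    cpl_mean, cpl_largest = characteristic_path_length(net)
    return NetworkMetrics(
        structure_id=net.structure_id,
        frame_index=net.frame_index,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=graph_density(net),
        entropy=graph_entropy(net),
        cpl_mean=cpl_mean,
        cpl_largest=cpl_largest,
        n_components=connected_components(net),
        clustering_coefficients=clustering_coefficient(net),
        n_ww_interactions=net.n_ww_interactions,
        n_wp_interactions=net.n_wp_interactions,
    )
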