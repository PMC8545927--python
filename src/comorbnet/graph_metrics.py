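"""Node centralities and global topology of undirected graphs.

Degree (DC), betweenness (BC) and closeness (CC) centrality per node,
plus the global measures used to characterise interaction networks:
average degree <k>, diameter D, mean shortest path length (mspl) and
average clustering coefficient (acc).  Betweenness is normalized by
(n-1)(n-2)/2 so that the centre of a star scores 1; closeness is the
strict (n-1)/sum-of-distances form, not the harmonic variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import pandas as pd


class DisconnectedGraphError(ValueError):
    """Centralities need a connected graph; extract the giant component."""


class CentralityRecord(NamedTuple):
    node: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class GlobalMetrics:
    """Global topology summary of a connected undirected graph."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    diameter: int
    mean_shortest_path_length: float
    avg_clustering_coefficient: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "diameter": self.diameter,
            "mean_shortest_path_length": self.mean_shortest_path_length,
            "avg_clustering_coefficient": self.avg_clustering_coefficient,
        }


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Return the largest connected component as a copied subgraph.

    Ties on size are broken deterministically by the smallest
    lexicographic node id in the component.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    best = min(
        nx.connected_components(graph),
        key=lambda comp: (-len(comp), min(map(str, comp))),
    )
    return graph.subgraph(best).copy()


def _require_connected(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not nx.is_connected(graph):
        raise DisconnectedGraphError(
            "graph is disconnected; apply giant_component() first"
        )


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality for every node.

    Returns a frame with columns ``node, degree, betweenness,
    closeness`` sorted by betweenness descending (degree descending,
    then node id, as tie-breaks).
    """
    _require_connected(graph)
    bc = nx.betweenness_centrality(graph, normalized=True)
    cc = nx.closeness_centrality(graph)
    df = pd.DataFrame(
        [
            CentralityRecord(str(v), graph.degree(v), bc[v], cc[v])
            for v in graph.nodes
        ]
    )
    return df.sort_values(
        ["betweenness", "degree", "node"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)


def global_metrics(graph: nx.Graph) -> GlobalMetrics:
    """Average degree, diameter, mspl and acc of a connected graph.

    The clustering coefficient of nodes with degree < 2 is 0 and such
    nodes are included in the average (the convention most network
    tools use; it lowers acc on sparse graphs).
    """
    _require_connected(graph)
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    if n > 1:
        mspl = nx.average_shortest_path_length(graph)
        diameter = nx.diameter(graph)
    else:
        mspl, diameter = 0.0, 0
    return GlobalMetrics(
        n_nodes=n,
        n_edges=m,
        avg_degree=2 * m / n,
        diameter=diameter,
        mean_shortest_path_length=mspl,
        avg_clustering_coefficient=nx.average_clustering(graph),
    )
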