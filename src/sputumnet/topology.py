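"""Per-node topology metrics under Cytoscape NetworkAnalyzer conventions.

Five metrics per node of the unsigned simple graph: degree, clustering
coefficient, closeness centrality, betweenness centrality and topological
coefficient.  Conventions match Cytoscape's NetworkAnalyzer, which is what
keystone screening panels in microbiome network studies report:

* closeness(v) = (|C|-1) / sum of distances from v within v's connected
  component C (0 for a singleton component);
* betweenness is normalized by (N-1)(N-2)/2 with N the component size, so
  values live in [0, 1] even in disconnected networks;
* the topological coefficient of v averages J(v, m)/degree(v) over every
  node m (m != v) sharing at least one neighbor with v, where J(v, m) is
  the number of shared neighbors plus one if v and m are adjacent; it is
  defined as 0 for nodes of degree <= 1.

Cross-component distances are never summed; all metrics are exact (no
sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .cooccurrence import CooccurrenceNetwork

__all__ = ["NodeMetrics", "node_metrics", "node_metrics_graph", "topological_coefficient"]


@dataclass(frozen=True)
class NodeMetrics:
    """The five-metric panel for one genus node."""

    genus: str
    degree: int
    clustering_coefficient: float
    closeness: float
    betweenness: float
    topological_coefficient: float

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "genus": self.genus,
            "degree": self.degree,
            "clustering_coefficient": self.clustering_coefficient,
            "closeness": self.closeness,
            "betweenness": self.betweenness,
            "topological_coefficient": self.topological_coefficient,
        }


def topological_coefficient(g: nx.Graph, v) -> float:
    """Cytoscape topological coefficient of node ``v`` in graph ``g``.

    TC(v) = mean over nodes m sharing >= 1 neighbor with v of
    J(v, m)/degree(v), with J(v, m) = |N(v) & N(m)| plus 1 when v and m are
    adjacent.  Defined as 0 when degree(v) <= 1 or no sharing node exists.
    """
    k = g.degree(v)
    if k <= 1:
        return 0.0
    neighbors = set(g[v])
    sharing: dict = {}
    for u in neighbors:
        for m in g[u]:
            if m != v:
                sharing[m] = sharing.get(m, 0) + 1
    if not sharing:
        return 0.0
    total = 0.0
    for m, shared in sharing.items():
        j = shared + (1 if g.has_edge(v, m) else 0)
        total += j / k
    return total / len(sharing)


def node_metrics_graph(g: nx.Graph) -> dict[str, NodeMetrics]:
    """Compute the five-metric panel for every node of an unsigned graph."""
    out: dict[str, NodeMetrics] = {}
    if g.number_of_nodes() == 0:
        return out
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        betweenness.update(nx.betweenness_centrality(sub, normalized=True))
    for v in g.nodes:
        out[v] = NodeMetrics(
            genus=v,
            degree=int(g.degree(v)),
            clustering_coefficient=float(clustering[v]),
            closeness=float(closeness[v]),
            betweenness=float(betweenness[v]),
            topological_coefficient=topological_coefficient(g, v),
        )
    return out


def node_metrics(net: CooccurrenceNetwork) -> dict[str, NodeMetrics]:
    """Five-metric panel for every genus in a co-occurrence network.

    Metrics are computed on the unsigned simple graph; sign information on
    the edges is ignored.  Returns an empty map for an empty network.
    """
    return node_metrics_graph(net.to_networkx())
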