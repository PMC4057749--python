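"""Topological profiling of the heteroreceptor network.

Degree statistics, the degree distribution P(k), local clustering C(n) and
its degree-conditional mean C(k), density, shortest paths, diameter,
connected components, relative connectivity f and edge share.  Conventions
follow common PPI-network practice: C(n) = 0 for nodes of degree < 2 and
those nodes count in the global mean; path statistics are over connected
unordered pairs only (isolated protomers contribute no infinite distances);
isolated nodes stay in N for every metric.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .interaction_data import HetNetGraph


def _nx(graph) -> nx.Graph:
    return graph.nx if isinstance(graph, HetNetGraph) else graph


def node_degree(graph) -> dict[str, int]:
    """Degree k of every node; the handshake identity Σk = 2E holds."""
    g = _nx(graph)
    return {n: d for n, d in g.degree()}


def degree_distribution(graph) -> dict[int, float]:
    """P(k) = (number of nodes with degree k) / N, including k = 0."""
    g = _nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    counts = Counter(d for _, d in g.degree())
    return {k: counts[k] / n for k in sorted(counts)}


def local_clustering(graph, node) -> float:
    """C(n) = 2·n_l / (k(k−1)) where n_l counts edges among n's neighbors.

    Defined as 0 for degree < 2 (the formula is undefined there).
    """
    g = _nx(graph)
    if node not in g:
        raise KeyError(f"unknown node: {node!r}")
    return nx.clustering(g, node)


def clustering_distribution(graph) -> dict[int, float]:
    """C(k): mean local clustering over nodes of degree k."""
    g = _nx(graph)
    cc = nx.clustering(g)
    by_k: dict[int, list[float]] = {}
    for node, d in g.degree():
        by_k.setdefault(d, []).append(cc[node])
    return {k: sum(v) / len(v) for k, v in sorted(by_k.items())}


def global_clustering(graph) -> float:
    """Network clustering coefficient: mean of C(n) over all N nodes."""
    g = _nx(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cc = nx.clustering(g)
    return sum(cc.values()) / len(cc)


def average_degree(graph) -> float:
    """Mean degree 2E/N."""
    g = _nx(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return 2 * g.number_of_edges() / g.number_of_nodes()


def density(graph) -> float:
    """D = average degree / (N − 1) = 2E / (N(N−1))."""
    g = _nx(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least two nodes")
    return 2 * g.number_of_edges() / (n * (n - 1))


def shortest_path_lengths(graph) -> dict:
    """All-pairs shortest-path distances (breadth-first search per node);
    only reachable targets appear."""
    g = _nx(graph)
    return {source: dict(lengths)
            for source, lengths in nx.all_pairs_shortest_path_length(g)}


def path_length_histogram(graph) -> dict[int, int]:
    """Histogram L → number of connected unordered pairs at distance L."""
    g = _nx(graph)
    index = {n: i for i, n in enumerate(g.nodes)}
    hist: Counter[int] = Counter()
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if index[source] < index[target]:
                hist[dist] += 1
    return dict(sorted(hist.items()))


def mean_path_length(graph) -> float:
    """Mean shortest-path distance over connected unordered pairs."""
    hist = path_length_histogram(graph)
    total = sum(hist.values())
    if total == 0:
        raise ValueError("no connected pairs")
    return sum(length * count for length, count in hist.items()) / total


def diameter(graph) -> int:
    """Maximum finite shortest-path distance."""
    hist = path_length_histogram(graph)
    if not hist:
        raise ValueError("no connected pairs")
    return max(hist)


def connected_components(graph) -> list[set]:
    """Connected components, largest first (ties by smallest member id)."""
    g = _nx(graph)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def relative_connectivity(graph) -> float:
    """f = |largest connected component| / N."""
    g = _nx(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return max(len(c) for c in nx.connected_components(g)) / g.number_of_nodes()


def edge_share(graph, subset) -> float:
    """Fraction of edges with at least one endpoint in ``subset``.

    For an independent set this equals (Σ degrees in subset) / E.
    """
    g = _nx(graph)
    subset = set(subset)
    if not subset:
        return 0.0
    missing = subset - set(g.nodes)
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(missing)}")
    e = g.number_of_edges()
    if e == 0:
        raise ValueError("graph has no edges")
    hit = sum(1 for a, b in g.edges if a in subset or b in subset)
    return hit / e


@dataclass
class DistributionProfile:
    """Everything the downstream model classification and report consume."""

    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    global_clustering: float
    relative_connectivity: float
    degree_distribution: dict[int, float]
    clustering_distribution: dict[int, float]
    path_length_histogram: dict[int, int] = field(default_factory=dict)
    mean_path_length: float | None = None
    diameter: int | None = None

    def scalar_metrics(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "average_degree": self.average_degree,
            "global_clustering": self.global_clustering,
            "relative_connectivity": self.relative_connectivity,
            "mean_path_length": self.mean_path_length,
            "diameter": self.diameter,
        }


def profile(graph) -> DistributionProfile:
    """Compute the full topological profile in one pass.

    Path statistics are left ``None`` when the graph has no connected pair.
    """
    g = _nx(graph)
    hist = path_length_histogram(g)
    total = sum(hist.values())
    return DistributionProfile(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=density(g),
        average_degree=average_degree(g),
        global_clustering=global_clustering(g),
        relative_connectivity=relative_connectivity(g),
        degree_distribution=degree_distribution(g),
        clustering_distribution=clustering_distribution(g),
        path_length_histogram=hist,
        mean_path_length=(sum(l * c for l, c in hist.items()) / total
                          if total else None),
        diameter=max(hist) if hist else None,
    )
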