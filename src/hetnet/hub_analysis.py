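"""Hub identification under four alternative criteria.

There is no consensus definition of a hub in protein-interaction networks,
so four are computed side by side: (1) the top high-degree slice of the
network (default: the highest 5% of nodes by degree, reported with the
realized degree cutoff), (2) degree > 5, (3) degree > 8, and (4) the
successive-subgraph relative-connectivity procedure, which walks the nodes
in decreasing-degree order, tracks the relative connectivity f of each
degree-ordered prefix subgraph, and places the hub/non-hub boundary at the
first rise of f (hubs connect mostly to non-hubs, so f falls while only
hubs are present and first rises when a connector node arrives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .interaction_data import HetNetGraph
from .topology import node_degree


@dataclass
class HubResult:
    """Outcome of one hub-selection criterion.

    ``hubs`` is ordered by decreasing degree, ties broken by ascending id.
    ``cutoff`` is the realized degree cutoff; ``f_trajectory`` is populated
    by the relative-connectivity criterion only.
    """

    criterion: str
    cutoff: int | None
    hubs: list[tuple[str, int]]
    f_trajectory: list[float] | None = None
    status: str = "ok"

    @property
    def hub_ids(self) -> list[str]:
        return [h for h, _ in self.hubs]

    def __len__(self) -> int:
        return len(self.hubs)


def _nx(graph) -> nx.Graph:
    return graph.nx if isinstance(graph, HetNetGraph) else graph


def _by_degree(degrees: dict[str, int], members) -> list[tuple[str, int]]:
    return sorted(((n, degrees[n]) for n in members),
                  key=lambda item: (-item[1], str(item[0])))


def hubs_degree_threshold(graph, t: int) -> HubResult:
    """Hubs are all nodes with degree strictly greater than ``t``."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    degrees = node_degree(graph)
    hubs = _by_degree(degrees, (n for n, d in degrees.items() if d > t))
    return HubResult(criterion=f"degree_gt{t}", cutoff=t, hubs=hubs)


def hubs_top_percentile(graph, q: float = 0.95) -> HubResult:
    """Hubs are the highest-degree ceil((1−q)·N) nodes, extended to ties.

    The realized cutoff is the degree of the last selected node; every node
    at or above the cutoff is a hub.  A graph whose degrees are all equal is
    flagged ``degenerate`` (every node ties for the top).
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    degrees = node_degree(graph)
    if not degrees:
        raise ValueError("empty graph")
    n_top = math.ceil((1 - q) * len(degrees))
    desc = sorted(degrees.values(), reverse=True)
    cutoff = desc[n_top - 1]
    hubs = _by_degree(degrees, (n for n, d in degrees.items() if d >= cutoff))
    status = "degenerate" if len(set(degrees.values())) == 1 else "ok"
    return HubResult(criterion="top95", cutoff=cutoff, hubs=hubs, status=status)


def hubs_relative_connectivity(graph) -> HubResult:
    """Successive-subgraph relative-connectivity hub criterion.

    Nodes are listed by decreasing degree (ties by ascending id) and added
    one at a time to an induced prefix subgraph G_k; f_k is the largest
    component of G_k over k.  The first k with f_k > f_{k−1} is the natural
    hub/non-hub boundary and the nodes of G_{k−1} are the hubs.  If f never
    rises the boundary does not exist and an empty hub set is returned with
    status ``no boundary found``.
    """
    g = _nx(graph)
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        raise ValueError("relative-connectivity criterion needs >=2 nodes and >=1 edge")
    degrees = {n: d for n, d in g.degree()}
    order = [n for n, _ in _by_degree(degrees, degrees)]

    # incremental union-find over the degree-ordered prefix
    parent: dict[str, str] = {}
    size: dict[str, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    added: set[str] = set()
    largest = 0
    trajectory: list[float] = []
    for k, node in enumerate(order, start=1):
        parent[node] = node
        size[node] = 1
        added.add(node)
        largest = max(largest, 1)
        for nbr in g.neighbors(node):
            if nbr not in added:
                continue
            ra, rb = find(node), find(nbr)
            if ra != rb:
                if size[ra] < size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                size[ra] += size[rb]
                largest = max(largest, size[ra])
        f_k = largest / k
        if trajectory and f_k > trajectory[-1]:
            hubs = _by_degree(degrees, order[: k - 1])
            cutoff = min(d for _, d in hubs)
            return HubResult(criterion="relative_connectivity", cutoff=cutoff,
                             hubs=hubs, f_trajectory=trajectory + [f_k])
        trajectory.append(f_k)
    return HubResult(criterion="relative_connectivity", cutoff=None, hubs=[],
                     f_trajectory=trajectory, status="no boundary found")


def nonhub_degree_one(graph) -> list[str]:
    """All protomers with exactly one interaction, sorted by id."""
    degrees = node_degree(graph)
    return sorted(n for n, d in degrees.items() if d == 1)
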