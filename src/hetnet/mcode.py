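"""Molecular Complex Detection (MCODE) dense-module search.

Three stages. (1) Vertex weighting: each node scoring at least
``degree_cutoff`` neighbors receives the core-clustering coefficient of its
closed neighborhood — the density of the highest k-core of N[v] — scaled by
that core's k.  (2) Complex prediction: seeding from the highest-weight
unassigned node, a breadth-first expansion recruits neighbors whose weight
is within ``node_score_cutoff`` (as a fraction) of the seed weight; every
node joins at most one complex, so clusters are node-disjoint.
(3) Post-processing: candidates lacking a ``k_core_filter``-core are
discarded; the optional fluff step (off by default) adds dense boundary
neighbors before the haircut iteratively strips members with fewer than two
within-cluster neighbors.  Complexes are scored density × size and ranked.

Defaults match the parameters commonly used for receptor-interaction
networks: degree cutoff 2, 2-core filter, haircut on, fluff off.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .interaction_data import HetNetGraph


def _nx(graph) -> nx.Graph:
    return graph.nx if isinstance(graph, HetNetGraph) else graph


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.k_core_filter < 1:
            raise ValueError("k_core_filter must be >= 1")


@dataclass(frozen=True)
class ClusterResult:
    """One detected module: members, density × size score, 1-based rank."""

    members: frozenset
    score: float
    rank: int
    seed: str
    density: float

    def __len__(self) -> int:
        return len(self.members)


def k_core(graph, k: int) -> set:
    """Maximal node set whose induced subgraph has minimum degree ≥ k.

    Computed by iterative pruning of under-degree nodes; may be empty.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    g = _nx(graph)
    degree = {n: d for n, d in g.degree()}
    alive = set(g.nodes)
    stack = [n for n in alive if degree[n] < k]
    while stack:
        node = stack.pop()
        if node not in alive:
            continue
        alive.discard(node)
        for nbr in g.neighbors(node):
            if nbr in alive:
                degree[nbr] -= 1
                if degree[nbr] < k:
                    stack.append(nbr)
    return alive


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weighting by the core-clustering coefficient.

    weight(v) = k_max × density of the k_max-core of the closed neighborhood
    N[v]; nodes with degree below ``degree_cutoff`` weigh 0.
    """
    g = _nx(graph)
    weights: dict = {}
    for node in g.nodes:
        if g.degree(node) < degree_cutoff:
            weights[node] = 0.0
            continue
        closed = set(g.neighbors(node)) | {node}
        sub = g.subgraph(closed)
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        if k_max == 0:
            weights[node] = 0.0
            continue
        core = sub.subgraph(n for n, c in core_numbers.items() if c >= k_max)
        weights[node] = k_max * _density(core)
    return weights


def predict_complexes(graph, weights: dict, node_score_cutoff: float = 0.2
                      ) -> list[tuple[frozenset, str]]:
    """Greedy seeded expansion into candidate complexes.

    Seeds are taken in decreasing weight (ties: higher degree, then
    ascending id); expansion admits unassigned neighbors whose weight is at
    least seed_weight × (1 − node_score_cutoff).  Returns (members, seed)
    pairs; deterministic.
    """
    g = _nx(graph)
    order = sorted(g.nodes,
                   key=lambda n: (-weights.get(n, 0.0), -g.degree(n), str(n)))
    assigned: set = set()
    complexes: list[tuple[frozenset, str]] = []
    for seed in order:
        if seed in assigned or weights.get(seed, 0.0) <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = [seed]
        assigned.add(seed)
        queue = [seed]
        while queue:
            current = queue.pop(0)
            for nbr in sorted(g.neighbors(current),
                              key=lambda n: (-weights.get(n, 0.0), str(n))):
                if nbr in assigned or weights.get(nbr, 0.0) < threshold:
                    continue
                assigned.add(nbr)
                members.append(nbr)
                queue.append(nbr)
        complexes.append((frozenset(members), seed))
    return complexes


def _haircut(g: nx.Graph, members: set) -> set:
    """Iteratively remove members with fewer than two within-cluster links."""
    members = set(members)
    changed = True
    while changed:
        changed = False
        sub = g.subgraph(members)
        trim = {n for n in members if sub.degree(n) < 2}
        if trim:
            members -= trim
            changed = True
    return members


def postprocess(graph, candidates, params: MCODEParams | None = None
                ) -> list[ClusterResult]:
    """Filter, fluff, haircut, score and rank candidate complexes.

    Candidates without a ``k_core_filter``-core are dropped.  Fluff (before
    haircut) adds unassigned boundary neighbors whose closed-neighborhood
    density exceeds ``fluff_threshold``.  If trimming disconnects a
    candidate, the component containing the seed is kept (the largest
    component when the seed itself was trimmed).  Ranking: decreasing
    score, then decreasing size, then ascending seed id.
    """
    params = params or MCODEParams()
    g = _nx(graph)
    assigned = {n for members, _ in candidates for n in members}
    kept: list[tuple[frozenset, str, float]] = []
    for members, seed in candidates:
        members = set(members)
        if not k_core(g.subgraph(members), params.k_core_filter):
            continue
        if params.fluff:
            boundary = set()
            for node in members:
                for nbr in g.neighbors(node):
                    if nbr in members or nbr in assigned or nbr in boundary:
                        continue
                    closed = set(g.neighbors(nbr)) | {nbr}
                    if _density(g.subgraph(closed)) > params.fluff_threshold:
                        boundary.add(nbr)
            members |= boundary
            assigned |= boundary
        if params.haircut:
            members = _haircut(g, members)
        if not members:
            continue
        comps = list(nx.connected_components(g.subgraph(members)))
        if len(comps) > 1:
            seed_comps = [c for c in comps if seed in c]
            if seed_comps:
                members = seed_comps[0]
            else:
                members = sorted(comps, key=lambda c: (-len(c), min(map(str, c))))[0]
        if not k_core(g.subgraph(members), params.k_core_filter):
            continue
        sub = g.subgraph(members)
        kept.append((frozenset(members), seed, _density(sub)))
    kept.sort(key=lambda item: (-item[2] * len(item[0]), -len(item[0]), str(item[1])))
    return [
        ClusterResult(members=members, score=dens * len(members),
                      rank=rank, seed=seed, density=dens)
        for rank, (members, seed, dens) in enumerate(kept, start=1)
    ]


def mcode(graph, params: MCODEParams | None = None) -> list[ClusterResult]:
    """Run the full MCODE pipeline and return ranked clusters."""
    params = params or MCODEParams()
    g = _nx(graph)
    weights = vertex_weights(g, params.degree_cutoff)
    candidates = predict_complexes(g, weights, params.node_score_cutoff)
    return postprocess(g, candidates, params)
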