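"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: clustering is
verified by explicit neighbor-pair enumeration, shortest paths by
Floyd–Warshall dynamic programming, the relative-connectivity trajectory by
recomputing components on every prefix from scratch.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest


# -- fixtures ------------------------------------------------------------

@pytest.fixture
def triangle() -> nx.Graph:
    return nx.complete_graph(3)


@pytest.fixture
def star4() -> nx.Graph:
    """K1,3: hub node 0, leaves 1..3."""
    return nx.star_graph(3)


@pytest.fixture
def path4() -> nx.Graph:
    return nx.path_graph(4)


@pytest.fixture
def kite() -> nx.Graph:
    """K4 with a pendant on vertex 3."""
    g = nx.complete_graph(4)
    g.add_edge(3, 4)
    return g


@pytest.fixture(scope="session")
def hetnet_like_graph():
    from hetnet import gen_hetnet_like

    return gen_hetnet_like(seed=7)


def random_small_graphs(n_graphs: int = 200, max_n: int = 30, seed: int = 12345):
    """Seeded stream of small Erdős–Rényi graphs (possibly disconnected)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.02, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        yield g


# -- oracles -------------------------------------------------------------

def clustering_oracle(g: nx.Graph, node) -> float:
    """C(n) by explicit enumeration of edges among neighbors."""
    nbrs = list(g.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v))
    return 2 * links / (k * (k - 1))


def floyd_warshall_oracle(g: nx.Graph) -> dict:
    """All-pairs distances by O(n^3) dynamic programming."""
    nodes = list(g.nodes)
    inf = float("inf")
    dist = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in g.edges:
        dist[u][v] = dist[v][u] = 1
    for w in nodes:
        for u in nodes:
            duw = dist[u][w]
            if duw == inf:
                continue
            for v in nodes:
                alt = duw + dist[w][v]
                if alt < dist[u][v]:
                    dist[u][v] = alt
    return dist


def kcore_oracle(g: nx.Graph, k: int) -> set:
    """k-core by repeated full rescans until stable (independent of the
    stack-based pruning in the implementation)."""
    alive = set(g.nodes)
    while True:
        bad = {n for n in alive
               if sum(1 for m in g.neighbors(n) if m in alive) < k}
        if not bad:
            return alive
        alive -= bad


def prefix_f_oracle(g: nx.Graph, order: list) -> list[float]:
    """f on every degree-ordered prefix, components recomputed from scratch."""
    out = []
    for k in range(1, len(order) + 1):
        sub = g.subgraph(order[:k])
        out.append(max(len(c) for c in nx.connected_components(sub)) / k)
    return out


def powerlaw_fit_oracle(points: dict) -> tuple[float, float, float]:
    """Normal-equation least squares on log10 points: (slope, intercept, R²)."""
    xs = [np.log10(k) for k, y in sorted(points.items()) if k > 0 and y > 0]
    ys = [np.log10(y) for k, y in sorted(points.items()) if k > 0 and y > 0]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = sum((y - (slope * x + intercept)) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - sy / n) ** 2 for y in ys)
    return slope, intercept, 1 - ss_res / ss_tot
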