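"""Seeded graph generators for exercising the pipeline.

Four kinds of networks: Erdős–Rényi random graphs, preferential-attachment
scale-free graphs, Ravasz-style hierarchical graphs (deterministic modular
replication, C(k) ≈ k^−1), and "HetNet-like" graphs realizing a prescribed
degree-sequence skeleton — node/edge totals, isolated-node and degree-1
counts, and an explicit list of top hub degrees — via stub matching with
edge-swap repair.  Identical kind + parameters + seed always reproduce the
identical edge list.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .interaction_data import Family, HetNetGraph

#: Family mix of the curated heteroreceptor network: ~82% class A (F1),
#: ~10% class B (F2), ~8% class C (F3).
DEFAULT_FAMILY_PROPORTIONS = (0.82, 0.10, 0.08)


def _ids(n: int, prefix: str = "R") -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _wrap(g: nx.Graph) -> HetNetGraph:
    for node in g.nodes:
        g.nodes[node].setdefault("family", Family.UNKNOWN)
    for _, _, data in g.edges(data=True):
        data.setdefault("methods", frozenset())
        data.setdefault("n_publications", 0)
        data.setdefault("controversial", False)
    return HetNetGraph(g)


def gen_random(n: int, p: float, seed: int = 0) -> HetNetGraph:
    """Erdős–Rényi G(n, p): each unordered pair is an edge with probability p."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = _ids(n)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if n > 1 and p > 0:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.shape[0]) < p
        g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu[mask], ju[mask]))
    return _wrap(g)


def gen_scale_free(n: int, m: int, seed: int = 0) -> HetNetGraph:
    """Preferential-attachment growth model.

    Starts from a complete clique on m+1 nodes; each subsequent node
    attaches m edges to distinct existing nodes chosen with probability
    proportional to their current degree.  E = m(n − m − 1) + C(m+1, 2).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < m + 1:
        raise ValueError("n must be > m")
    rng = np.random.default_rng(seed)
    ids = _ids(n)
    g = nx.Graph()
    g.add_nodes_from(ids[: m + 1])
    g.add_edges_from((ids[i], ids[j]) for i in range(m + 1) for j in range(i + 1, m + 1))
    # degree-weighted target pool: each node appears once per incident edge
    pool: list[int] = [i for i in range(m + 1) for _ in range(m)]
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(pool[rng.integers(len(pool))])
        for t in targets:
            g.add_edge(ids[new], ids[t])
            pool.append(t)
        pool.extend([new] * m)
    return _wrap(g)


def gen_hierarchical(levels: int, base_size: int, seed: int = 0) -> HetNetGraph:
    """Deterministic Ravasz-style hierarchical modular graph.

    A base clique is replicated base_size − 1 times per level and every
    peripheral node of the replicas is wired to the root hub, yielding
    base_size^levels nodes, a heavy-tailed degree sequence and a clustering
    spectrum C(k) that decays roughly as k^−1.  The construction is
    deterministic; ``seed`` is accepted for interface uniformity only.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if base_size < 4:
        raise ValueError("base_size must be >= 4")
    g = nx.complete_graph(base_size)
    root = 0
    peripheral = set(range(1, base_size))
    for _ in range(2, levels + 1):
        template = g.copy()
        n_prev = template.number_of_nodes()
        new_peripheral: set[int] = set()
        for copy in range(1, base_size):
            offset = copy * n_prev
            g.add_edges_from((u + offset, v + offset) for u, v in template.edges)
            for p in peripheral:
                g.add_edge(p + offset, root)
            new_peripheral |= {p + offset for p in peripheral}
        peripheral = new_peripheral
    ids = _ids(g.number_of_nodes(), prefix="H")
    g = nx.relabel_nodes(g, {i: ids[i] for i in g.nodes})
    return _wrap(g)


class UnsatisfiableConstraints(ValueError):
    """The requested degree-sequence constraints cannot be realized."""


def _build_degree_sequence(n, e, n_isolated, n_degree1, top_degrees):
    top = sorted(top_degrees, reverse=True)
    n_filler = n - n_isolated - n_degree1 - len(top)
    if n_filler < 0:
        raise UnsatisfiableConstraints(
            f"n_isolated + n_degree1 + len(top_degrees) = "
            f"{n_isolated + n_degree1 + len(top)} exceeds n = {n}")
    specified = n_degree1 + sum(top)
    remainder = 2 * e - specified
    if n_filler == 0:
        if remainder != 0:
            raise UnsatisfiableConstraints(
                f"degree sum {specified} != 2e = {2 * e} with no filler nodes "
                f"(handshake violation)")
        fillers: list[int] = []
    else:
        cap = max(2, (min(top) - 1) if top else 2 * e)
        if remainder < 2 * n_filler or remainder > cap * n_filler:
            raise UnsatisfiableConstraints(
                f"filler degree sum {remainder} not realizable with "
                f"{n_filler} nodes of degree in [2, {cap}]")
        base, extra = divmod(remainder - 2 * n_filler, n_filler)
        fillers = [2 + base + (1 if i < extra else 0) for i in range(n_filler)]
        if max(fillers) > cap:
            raise UnsatisfiableConstraints(
                f"filler degree {max(fillers)} exceeds cap {cap}")
    seq = top + fillers + [1] * n_degree1 + [0] * n_isolated
    if max(seq, default=0) > n - n_isolated - 1:
        raise UnsatisfiableConstraints(
            f"top degree {max(seq)} exceeds the {n - n_isolated} connectable nodes")
    return seq


def _realize_degree_sequence(seq: list[int], rng: np.random.Generator,
                             max_restarts: int = 50) -> nx.Graph:
    """Configuration-model realization: stub matching, then double-edge-swap
    repair of the leftover conflicting stubs, restarting on failure."""
    n = len(seq)
    for _ in range(max_restarts):
        stubs = np.repeat(np.arange(n), seq)
        rng.shuffle(stubs)
        edges: set[tuple[int, int]] = set()
        leftover: list[int] = []
        for i in range(0, len(stubs) - 1, 2):
            u, v = int(stubs[i]), int(stubs[i + 1])
            key = (min(u, v), max(u, v))
            if u == v or key in edges:
                leftover += [u, v]
            else:
                edges.add(key)
        ok = True
        for i in range(0, len(leftover) - 1, 2):
            u, v = leftover[i], leftover[i + 1]
            # consume stubs u and v by splitting a random existing edge (x, y)
            repaired = False
            edge_list = list(edges)
            for attempt in range(10000):
                x, y = edge_list[rng.integers(len(edge_list))]
                if len({u, v, x, y}) < 4:
                    continue
                e1 = (min(u, x), max(u, x))
                e2 = (min(v, y), max(v, y))
                if e1 in edges or e2 in edges:
                    continue
                edges.discard((x, y))
                edges.update((e1, e2))
                repaired = True
                break
            if not repaired:
                ok = False
                break
        if not ok:
            continue
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        if [g.degree(i) for i in range(n)] == list(seq):
            return g
    raise UnsatisfiableConstraints(
        "could not realize the degree sequence as a simple graph")


def _assign_families(g: nx.Graph, rng: np.random.Generator,
                     proportions=DEFAULT_FAMILY_PROPORTIONS,
                     intrafamily_bias: float = 0.8) -> None:
    """Assign F1/F2/F3 labels at the given proportions, then hill-climb
    label swaps to favor intrafamily edges (bias scales the search effort)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    n2 = round(proportions[1] * n)
    n3 = round(proportions[2] * n)
    labels = ([Family.F1] * (n - n2 - n3) + [Family.F2] * n2 + [Family.F3] * n3)
    order = rng.permutation(n)
    fam = {nodes[order[i]]: labels[i] for i in range(n)}

    def intra_gain(node, new_fam):
        old = fam[node]
        gain = 0
        for nbr in g.neighbors(node):
            if fam[nbr] is new_fam:
                gain += 1
            if fam[nbr] is old:
                gain -= 1
        return gain

    for _ in range(int(intrafamily_bias * 20 * n)):
        i, j = rng.integers(n), rng.integers(n)
        a, b = nodes[int(i)], nodes[int(j)]
        if fam[a] is fam[b]:
            continue
        delta = intra_gain(a, fam[b]) + intra_gain(b, fam[a])
        if fam[b] is not fam[a] and g.has_edge(a, b):
            delta -= 2  # the a–b edge cannot become intrafamily via a swap
        if delta > 0:
            fam[a], fam[b] = fam[b], fam[a]
    for node in nodes:
        g.nodes[node]["family"] = fam[node]


def gen_hetnet_like(n: int = 156, e: int = 260, n_isolated: int = 23,
                    n_degree1: int = 57,
                    top_degrees=(17, 17, 13, 12, 11, 10, 10, 10, 10),
                    seed: int = 0, assign_families: bool = True,
                    family_proportions=DEFAULT_FAMILY_PROPORTIONS,
                    intrafamily_bias: float = 0.8) -> HetNetGraph:
    """Generate a graph matching a heteroreceptor-network summary skeleton.

    The degree sequence contains exactly the given ``top_degrees``,
    ``n_degree1`` degree-1 nodes and ``n_isolated`` isolated nodes; the
    remaining nodes are filled with mid-range degrees (between 2 and one
    below the smallest top degree) so the total is 2e.  Defaults emulate
    the curated network's printed summary: 156 protomers, 260 heteromer
    pairs, 23 disconnected protomers, 57 single-partner protomers and the
    nine highest printed hub degrees.  All constraints are reproduced
    exactly or an error names the violated arithmetic condition.
    """
    seq = _build_degree_sequence(n, e, n_isolated, n_degree1, list(top_degrees))
    rng = np.random.default_rng(seed)
    g_int = _realize_degree_sequence(seq, rng)
    ids = _ids(n)
    g = nx.relabel_nodes(g_int, {i: ids[i] for i in range(n)})
    if assign_families:
        _assign_families(g, rng, family_proportions, intrafamily_bias)
    return _wrap(g)
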