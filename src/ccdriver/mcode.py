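"""MCODE-style dense-module detection.

Vertex weighting, complex expansion and the post-hoc retention filter are
implemented from scratch on simple undirected graphs:

1. Each vertex is weighted by the highest k-core of its closed neighborhood:
   ``weight = k_max * density(core)``, where the core is the subgraph of the
   closed neighborhood whose k-core number equals ``k_max``.
2. Complexes grow breadth-first from unvisited seeds in descending weight
   order (ties broken lexicographically); a neighbor joins when its weight is
   at least ``seed_weight * (1 - vwp)``. Included nodes are marked visited,
   so returned complexes are node-disjoint.
3. The haircut iteratively removes nodes with within-complex degree < 2;
   complexes reduced below two nodes are discarded.

The retention filter keeps complexes whose module k-core number exceeds a
cutoff (default: > 5) and whose node degree statistic exceeds a cutoff
(default: mean within-module degree > 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "mcode_vertex_weights",
    "mcode_find_complexes",
    "filter_modules",
    "ModuleCluster",
]


@dataclass(frozen=True)
class ModuleCluster:
    node_set: frozenset
    seed_node: str
    mcode_score: float
    kcore_max: int
    avg_within_degree: float
    min_within_degree: int
    seed_degree: int

    @property
    def size(self) -> int:
        return len(self.node_set)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _max_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k-core number and the corresponding core subgraph."""
    if g.number_of_nodes() == 0:
        return 0, g
    core = nx.core_number(g)
    k_max = max(core.values())
    nodes = [v for v, k in core.items() if k == k_max]
    return k_max, g.subgraph(nodes)


def mcode_vertex_weights(net: nx.Graph) -> dict:
    """Core-clustering-coefficient weight for every vertex.

    weight(v) = k_max(closed neighborhood of v) * density(its highest k-core);
    isolated vertices weigh 0.
    """
    weights: dict = {}
    for v in net.nodes():
        nbrs = list(net.neighbors(v))
        if not nbrs:
            weights[v] = 0.0
            continue
        closed = net.subgraph([v, *nbrs])
        k_max, core = _max_core(closed)
        weights[v] = float(k_max) * _density(core)
    return weights


def _haircut(g: nx.Graph) -> set:
    """Iteratively strip nodes with degree < 2; returns surviving node set."""
    sub = nx.Graph(g)
    while True:
        low = [v for v, d in sub.degree() if d < 2]
        if not low:
            return set(sub.nodes())
        sub.remove_nodes_from(low)
        if sub.number_of_nodes() == 0:
            return set()


def _cluster_from_nodes(net: nx.Graph, nodes: set, seed) -> ModuleCluster:
    sub = net.subgraph(nodes)
    degs = dict(sub.degree())
    k_max, _ = _max_core(sub)
    return ModuleCluster(
        node_set=frozenset(nodes),
        seed_node=seed,
        mcode_score=_density(sub) * len(nodes),
        kcore_max=k_max,
        avg_within_degree=sum(degs.values()) / len(nodes),
        min_within_degree=min(degs.values()),
        seed_degree=degs.get(seed, 0),
    )


def mcode_find_complexes(
    net: nx.Graph,
    weights: dict | None = None,
    *,
    vwp: float = 0.2,
    haircut: bool = True,
) -> list[ModuleCluster]:
    """Seed-and-expand complex detection (fluff off, loops ignored)."""
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must lie in [0, 1)")
    if weights is None:
        weights = mcode_vertex_weights(net)
    missing = set(net.nodes()) - set(weights)
    if missing:
        raise ValueError(f"weights missing for nodes: {sorted(map(str, missing))[:5]}")

    order = sorted(net.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()  # nodes in returned complexes, plus spent seeds
    clusters: list[ModuleCluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for w in sorted(net.neighbors(u), key=str):
                if w not in visited and w not in members and weights[w] >= threshold:
                    members.add(w)
                    queue.append(w)
        if haircut:
            members = _haircut(net.subgraph(members))
        visited.add(seed)
        if len(members) < 2:
            continue  # trimmed/discarded nodes stay available to later seeds
        visited |= members
        clusters.append(_cluster_from_nodes(net, members, seed))
    clusters.sort(key=lambda c: (-c.mcode_score, str(c.seed_node)))
    return clusters


def filter_modules(
    clusters: list[ModuleCluster],
    *,
    kcore_min_exclusive: int = 5,
    degree_min_exclusive: float = 5.0,
    degree_statistic: str = "mean",
) -> list[ModuleCluster]:
    """Retain modules with k-core number > cutoff and node degree > cutoff.

    ``degree_statistic`` selects which within-module degree is compared:
    "mean" (default, the result-panel statistic), "min", or "seed".
    """
    stat = {
        "mean": lambda c: c.avg_within_degree,
        "min": lambda c: float(c.min_within_degree),
        "seed": lambda c: float(c.seed_degree),
    }
    if degree_statistic not in stat:
        raise ValueError(f"unknown degree_statistic: {degree_statistic!r}")
    kept = [
        c
        for c in clusters
        if c.kcore_max > kcore_min_exclusive
        and stat[degree_statistic](c) > degree_min_exclusive
    ]
    kept.sort(key=lambda c: (-c.mcode_score, str(c.seed_node)))
    return kept
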