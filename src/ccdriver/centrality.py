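"""Twelve node-centrality coefficients and the top-10 / >=5-of-12 hub rule.

Metrics (all on simple undirected graphs; isolated nodes score 0 on every
path-based metric):

- Degree: number of neighbors.
- Closeness: harmonic form, sum over reachable w of 1/d(v, w), so it stays
  defined on disconnected graphs.
- Betweenness: sum over unordered pairs s != v != t of the fraction of
  shortest s-t paths through v (unnormalized).
- Stress: same sum, counting paths instead of fractions.
- Eccentricity: reciprocal of the maximum distance within v's component, so
  higher means more central, uniform with the other metrics; the raw
  eccentricity is kept alongside.
- Radiality: sum over component members w != v of
  (component_diameter + 1 - d(v, w)) / (|component| - 1).
- ClusteringCoefficient: local clustering.
- MCC (maximal clique centrality): sum over maximal cliques of size >= 2
  containing v of (|clique| - 1)!; this reduces to the degree when v's
  neighborhood is edgeless.
- MNC: size of the largest connected component of the open-neighborhood
  subgraph G[N(v)].
- DMNC: edges/nodes**1.7 of that same component.
- BottleNeck: over breadth-first shortest-path trees rooted at every node s
  of a component with >= 2 nodes (parent = neighbor at distance d-1 with the
  lexicographically smallest label, for determinism), count the trees in
  which v's subtree holds more than a quarter of the tree's nodes.
- EPC (edge percolated component): mean, over seeded random realizations in
  which each edge is kept independently with a retention probability, of the
  number of other nodes reachable from v. With retention 1 this equals
  (component size - 1) exactly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _sp_components

METRICS = (
    "Degree",
    "Closeness",
    "Betweenness",
    "Stress",
    "Eccentricity",
    "Radiality",
    "ClusteringCoefficient",
    "MCC",
    "MNC",
    "DMNC",
    "EPC",
    "BottleNeck",
)

__all__ = [
    "METRICS",
    "CentralityTable",
    "HubCall",
    "compute_centralities",
    "top_k_sets",
    "call_hubs",
]


@dataclass(frozen=True)
class CentralityTable:
    """Per-node scores for the 12 metrics plus EPC bookkeeping."""

    scores: pd.DataFrame  # index: node label (str), columns: METRICS (+ RawEccentricity)
    rng_seed: int
    epc_realizations: int
    epc_retention: float

    def __post_init__(self) -> None:
        missing = set(METRICS) - set(self.scores.columns)
        if missing:
            raise ValueError(f"missing metrics: {sorted(missing)}")

    @property
    def nodes(self) -> list[str]:
        return list(self.scores.index)


@dataclass(frozen=True)
class HubCall:
    node: str
    n_top_memberships: int
    memberships: frozenset  # metric names
    is_hub: bool


def _bfs_lengths_and_counts(adj: list[list[int]], source: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (BFS)."""
    n = len(adj)
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0
    sigma[source] = 1.0
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        for w in adj[u]:
            if math.isinf(dist[w]):
                dist[w] = du + 1
                q.append(w)
            if dist[w] == du + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _stress(adj: list[list[int]]) -> np.ndarray:
    """Stress centrality: number of shortest paths through each node."""
    n = len(adj)
    D = np.empty((n, n))
    S = np.empty((n, n))
    for s in range(n):
        D[s], S[s] = _bfs_lengths_and_counts(adj, s)
    stress = np.zeros(n)
    for v in range(n):
        through = D[:, v][:, None] + D[v, :][None, :]  # d(s,v)+d(v,t)
        on_path = np.isfinite(D) & (through == D)
        paths = S[:, v][:, None] * S[v, :][None, :]
        on_path[v, :] = False
        on_path[:, v] = False
        np.fill_diagonal(on_path, False)
        stress[v] = paths[on_path].sum() / 2.0  # unordered pairs
    return stress


def _bottleneck(g: nx.Graph, nodes: list) -> dict:
    """BottleNeck scores via deterministic BFS shortest-path trees."""
    score = {v: 0 for v in nodes}
    for comp in nx.connected_components(g):
        comp = sorted(comp, key=str)
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for s in comp:
            dist = nx.single_source_shortest_path_length(sub, s)
            # parent = neighbor one step closer, smallest label
            children: dict = {v: [] for v in comp}
            order = sorted(dist, key=lambda v: (dist[v], str(v)))
            for v in order:
                if v == s:
                    continue
                parent = min(
                    (u for u in sub.neighbors(v) if dist[u] == dist[v] - 1), key=str
                )
                children[parent].append(v)
            size = {v: 1 for v in comp}
            for v in reversed(order):
                for c in children[v]:
                    size[v] += size[c]
            n_tree = len(comp)
            for v in comp:
                if size[v] > n_tree / 4.0:
                    score[v] += 1
    return score


def _epc(
    g: nx.Graph, nodes: list, realizations: int, retention: float, seed: int
) -> dict:
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([[index[u], index[v]] for u, v in g.edges()], dtype=np.int64)
    n = len(nodes)
    totals = np.zeros(n)
    rng = np.random.default_rng(seed)
    for _ in range(realizations):
        if edges.size:
            keep = rng.random(len(edges)) < retention
            kept = edges[keep]
        else:
            kept = edges
        if kept.size:
            data = np.ones(len(kept))
            mat = csr_matrix((data, (kept[:, 0], kept[:, 1])), shape=(n, n))
            _, labels = _sp_components(mat, directed=False)
            sizes = np.bincount(labels, minlength=n)
            totals += sizes[labels] - 1
    return {v: totals[index[v]] / realizations for v in nodes}


def compute_centralities(
    net: nx.Graph,
    *,
    epc_realizations: int = 1000,
    epc_retention: float = 0.5,
    seed: int = 0,
) -> CentralityTable:
    """Compute all 12 centrality coefficients for every node of ``net``."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[w] for w in net.neighbors(v)] for v in nodes]
    n = len(nodes)

    degree = {v: net.degree(v) for v in nodes}
    clustering = nx.clustering(net)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    stress_arr = _stress(adj)
    stress = {v: float(stress_arr[index[v]]) for v in nodes}

    closeness: dict = {}
    eccentricity_score: dict = {}
    raw_ecc: dict = {}
    radiality: dict = {}
    for comp in nx.connected_components(net):
        comp = sorted(comp, key=str)
        sub = net.subgraph(comp)
        if len(comp) == 1:
            v = comp[0]
            closeness[v] = 0.0
            eccentricity_score[v] = 0.0
            raw_ecc[v] = 0
            radiality[v] = 0.0
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in lengths.values())
        for v in comp:
            dv = lengths[v]
            closeness[v] = sum(1.0 / d for w, d in dv.items() if w != v)
            ecc = max(dv.values())
            raw_ecc[v] = int(ecc)
            eccentricity_score[v] = 1.0 / ecc
            radiality[v] = sum(
                (diam + 1 - d) for w, d in dv.items() if w != v
            ) / (len(comp) - 1)

    # clique-based: one pass over maximal cliques
    mcc = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(net):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += contrib

    mnc: dict = {}
    dmnc: dict = {}
    for v in nodes:
        nbrs = list(net.neighbors(v))
        if not nbrs:
            mnc[v] = 0.0
            dmnc[v] = 0.0
            continue
        nbr_sub = net.subgraph(nbrs)
        comps = sorted(
            nx.connected_components(nbr_sub),
            key=lambda c: (-len(c), str(sorted(map(str, c))[0])),
        )
        best = nbr_sub.subgraph(comps[0])
        mnc[v] = float(best.number_of_nodes())
        if best.number_of_nodes() >= 2:
            dmnc[v] = best.number_of_edges() / best.number_of_nodes() ** 1.7
        else:
            dmnc[v] = 0.0

    bottleneck = _bottleneck(net, nodes)
    epc = _epc(net, nodes, epc_realizations, epc_retention, seed)

    frame = pd.DataFrame(
        {
            "Degree": [float(degree[v]) for v in nodes],
            "Closeness": [closeness[v] for v in nodes],
            "Betweenness": [float(betweenness[v]) for v in nodes],
            "Stress": [stress[v] for v in nodes],
            "Eccentricity": [eccentricity_score[v] for v in nodes],
            "Radiality": [radiality[v] for v in nodes],
            "ClusteringCoefficient": [float(clustering[v]) for v in nodes],
            "MCC": [mcc[v] for v in nodes],
            "MNC": [mnc[v] for v in nodes],
            "DMNC": [dmnc[v] for v in nodes],
            "EPC": [float(epc[v]) for v in nodes],
            "BottleNeck": [float(bottleneck[v]) for v in nodes],
            "RawEccentricity": [float(raw_ecc[v]) for v in nodes],
        },
        index=[str(v) for v in nodes],
    )
    return CentralityTable(
        scores=frame,
        rng_seed=seed,
        epc_realizations=epc_realizations,
        epc_retention=epc_retention,
    )


def top_k_sets(
    table: CentralityTable,
    *,
    k: int = 10,
    candidates: set | None = None,
) -> dict[str, set]:
    """Per-metric sets of nodes with competition rank <= k.

    Ties at the boundary are all included, so a set may exceed ``k``. When
    ``candidates`` is given, ranking is restricted to those nodes (the
    module-scoped hub workflow). Graphs smaller than ``k`` return every node.
    """
    frame = table.scores
    if candidates is not None:
        frame = frame.loc[[v for v in frame.index if v in candidates]]
    sets: dict[str, set] = {}
    for metric in METRICS:
        col = frame[metric]
        if len(col) <= k:
            sets[metric] = set(col.index)
            continue
        # competition rank: 1 + number of strictly greater scores
        cutoff = col.sort_values(ascending=False).iloc[k - 1]
        sets[metric] = set(col.index[col >= cutoff])
    return sets


def call_hubs(top_sets: dict[str, set], *, min_metrics: int = 5) -> list[HubCall]:
    """Consensus hub calls: a node is a hub when it sits in the top-k of at
    least ``min_metrics`` of the 12 metrics."""
    if set(top_sets) != set(METRICS):
        raise ValueError("expected exactly the 12 metric sets")
    nodes = set().union(*top_sets.values())
    calls = []
    for v in nodes:
        member = frozenset(m for m in METRICS if v in top_sets[m])
        calls.append(
            HubCall(
                node=v,
                n_top_memberships=len(member),
                memberships=member,
                is_hub=len(member) >= min_metrics,
            )
        )
    calls.sort(key=lambda h: (-h.n_top_memberships, str(h.node)))
    return calls
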