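"""DEG interaction network construction and topology statistics.

The network is the subgraph of a user-supplied interactome induced on the DEG
symbols: every DEG becomes a node (isolated DEGs stay as singletons, so they
count toward connected components), and an interactome edge is kept when both
endpoints are DEGs. Graphs are simple and undirected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .deg import DEGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "topology_report",
    "scale_free_fit",
    "TopologyReport",
    "PowerLawFit",
    "largest_component",
]


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    r2: float
    is_scale_free: bool
    reason: str = ""


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    char_path_length: float
    clustering_coefficient: float
    clustering_coefficient_incl_low_degree: float
    n_connected_components: int
    n_components_excluding_singletons: int
    powerlaw_gamma: float
    powerlaw_r2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def build_network(
    degs: Sequence[DEGRecord],
    interactome_edges: Iterable[tuple[str, str]],
) -> nx.Graph:
    """Induce the DEG network from an interactome edge list.

    Node set = DEG symbols (with ``log2fc`` and ``direction`` attributes);
    edge set = interactome edges with both endpoints in the DEG set. Edges
    touching unknown symbols are dropped (count logged); self-loops and
    duplicate edges are discarded.
    """
    degs = list(degs)
    if not degs:
        raise ValueError("empty DEG list")
    g = nx.Graph()
    n_unnamed = 0
    for d in degs:
        if not d.symbol:
            n_unnamed += 1
            continue
        if d.symbol not in g:
            g.add_node(d.symbol, log2fc=d.log2fc, direction=d.direction)
    if n_unnamed:
        logger.info("skipped %d DEG record(s) without a gene symbol", n_unnamed)
    if g.number_of_nodes() == 0:
        raise ValueError("no DEG records with gene symbols")
    n_dropped = 0
    for u, v in interactome_edges:
        if u == v:
            continue
        if u in g and v in g:
            g.add_edge(u, v)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d interactome edge(s) outside the DEG set", n_dropped)
    return g


def largest_component(g: nx.Graph) -> nx.Graph:
    """Largest connected component (ties: more edges, then smallest node label)."""
    comps = [g.subgraph(c) for c in nx.connected_components(g)]
    comps.sort(
        key=lambda s: (
            -s.number_of_nodes(),
            -s.number_of_edges(),
            str(sorted(map(str, s.nodes()))[0]),
        )
    )
    return comps[0]


def topology_report(net: nx.Graph) -> TopologyReport:
    """NetworkAnalyzer-style topology summary.

    Diameter and characteristic path length are computed on the largest
    connected component (finite values for disconnected graphs). The mean
    local clustering coefficient is reported both over nodes of degree >= 2
    and over all nodes (degree-<2 nodes contributing 0).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = net.number_of_nodes()
    m = net.number_of_edges()
    comps = list(nx.connected_components(net))
    lcc = largest_component(net)
    if lcc.number_of_nodes() > 1:
        diameter = nx.diameter(lcc)
        cpl = nx.average_shortest_path_length(lcc)
    else:
        diameter = 0
        cpl = 0.0
    clustering = nx.clustering(net)
    high = [c for v, c in clustering.items() if net.degree(v) >= 2]
    cc_high = float(np.mean(high)) if high else 0.0
    cc_all = float(np.mean([clustering[v] if net.degree(v) >= 2 else 0.0 for v in net]))
    fit = scale_free_fit(net, strict=False)
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        avg_neighbors=2.0 * m / n,
        diameter=int(diameter),
        char_path_length=float(cpl),
        clustering_coefficient=cc_high,
        clustering_coefficient_incl_low_degree=cc_all,
        n_connected_components=len(comps),
        n_components_excluding_singletons=sum(1 for c in comps if len(c) > 1),
        powerlaw_gamma=fit.gamma,
        powerlaw_r2=fit.r2,
    )


def scale_free_fit(net: nx.Graph, *, strict: bool = True) -> PowerLawFit:
    """Power-law check on the degree distribution.

    Least-squares line on log10(degree) vs log10(P(degree)) over degree bins
    with nonzero counts (degree >= 1 nodes only); ``gamma`` is the negated
    slope. The network is called scale-free when R^2 >= 0.8 and gamma lies in
    [1, 4] — a pragmatic screening convention, not a formal hypothesis test.
    Degenerate degree distributions (fewer than three distinct degrees) are
    flagged not-fittable.
    """
    degrees = np.array([d for _, d in net.degree() if d >= 1], dtype=float)
    if degrees.size < 10:
        if strict:
            raise ValueError("need at least 10 nodes with degree >= 1")
        return PowerLawFit(float("nan"), float("nan"), False, "too few connected nodes")
    values, counts = np.unique(degrees, return_counts=True)
    if values.size < 3:
        return PowerLawFit(
            float("nan"), float("nan"), False, "degenerate degree distribution"
        )
    pk = counts / degrees.size
    res = stats.linregress(np.log10(values), np.log10(pk))
    gamma = -float(res.slope)
    r2 = float(res.rvalue**2)
    ok = bool(r2 >= 0.8 and 1.0 <= gamma <= 4.0)
    return PowerLawFit(gamma, r2, ok, "" if ok else "fit below scale-free criterion")
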