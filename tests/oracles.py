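"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written by exhaustive enumeration (simple-path listing,
subset scans) on purpose, so it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math


def all_simple_paths(edges: set, nodes: list, s, t) -> list:
    """Every simple path from s to t, by DFS over the edge set."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    paths = []

    def walk(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for w in adj[last]:
            if w not in path:
                path.append(w)
                walk(path)
                path.pop()

    walk([s])
    return paths


def shortest_path_profile(edges: set, nodes: list):
    """dist[s][t], count of shortest paths, and per-node through-counts."""
    dist = {s: {} for s in nodes}
    count = {s: {} for s in nodes}
    through = {s: {t: {} for t in nodes} for s in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(edges, nodes, s, t)
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        best = [p for p in paths if len(p) - 1 == d]
        dist[s][t] = dist.setdefault(t, {})[s] = d
        dist[t][s] = d
        count[s][t] = count[t][s] = len(best)
        thr = {}
        for p in best:
            for v in p[1:-1]:
                thr[v] = thr.get(v, 0) + 1
        through[s][t] = thr
        through[t][s] = thr
    return dist, count, through


def betweenness_and_stress(edges: set, nodes: list):
    dist, count, through = shortest_path_profile(edges, nodes)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in count.get(s, {}):
            continue
        for v, c in through[s][t].items():
            bet[v] += c / count[s][t]
            stress[v] += c
    return bet, stress


def distance_metrics(edges: set, nodes: list):
    """Harmonic closeness, eccentricity score (1/ecc), radiality."""
    dist, _, _ = shortest_path_profile(edges, nodes)
    # connected components from finite distances
    comp_of = {}
    for v in nodes:
        if v in comp_of:
            continue
        comp = {v} | set(dist[v].keys())
        for w in comp:
            comp_of[w] = frozenset(comp)
    closeness, ecc_score, radiality = {}, {}, {}
    for v in nodes:
        ds = dist[v]
        closeness[v] = sum(1.0 / d for d in ds.values())
        comp = comp_of[v]
        if len(comp) == 1:
            ecc_score[v] = 0.0
            radiality[v] = 0.0
            continue
        ecc = max(ds[w] for w in comp if w != v)
        ecc_score[v] = 1.0 / ecc
        diam = max(
            dist[a][b] for a, b in itertools.combinations(sorted(comp, key=str), 2)
        )
        radiality[v] = sum(diam + 1 - ds[w] for w in comp if w != v) / (len(comp) - 1)
    return closeness, ecc_score, radiality


def neighborhood_metrics(edges: set, nodes: list):
    """MNC and DMNC via explicit neighborhood-subgraph component scan."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    mnc, dmnc = {}, {}
    for v in nodes:
        nbrs = sorted(adj[v], key=str)
        if not nbrs:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        sub_edges = {(a, b) for a, b in edges if a in adj[v] and b in adj[v]}
        # components among neighbors
        seen, comps = set(), []
        for start in nbrs:
            if start in seen:
                continue
            comp, stack = {start}, [start]
            while stack:
                u = stack.pop()
                for a, b in sub_edges:
                    w = b if a == u else a if b == u else None
                    if w is not None and w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            comps.append(comp)
        best = max(comps, key=lambda c: (len(c), str(sorted(map(str, c))[0])))
        e = sum(1 for a, b in sub_edges if a in best and b in best)
        mnc[v] = float(len(best))
        dmnc[v] = e / len(best) ** 1.7 if len(best) >= 2 else 0.0
    return mnc, dmnc


def mcc(edges: set, nodes: list):
    """Maximal-clique centrality via subset enumeration."""
    eset = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in eset for p in itertools.combinations(sub, 2))

    cliques = [
        set(sub)
        for r in range(2, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if is_clique(sub)
    ]
    maximal = [
        c
        for c in cliques
        if not any(c < d for d in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def kcore_number(edges: set, nodes: list) -> int:
    """Largest k with a nonempty k-core, by subset scan (|nodes| <= ~14)."""
    best = 0
    node_list = list(nodes)
    for r in range(2, len(node_list) + 1):
        for sub in itertools.combinations(node_list, r):
            subset = set(sub)
            deg = {v: 0 for v in subset}
            for u, v in edges:
                if u in subset and v in subset:
                    deg[u] += 1
                    deg[v] += 1
            best = max(best, min(deg.values()))
    return best


def bh_reject(pvals, alpha: float) -> set:
    """Benjamini-Hochberg step-up rejection set, straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * alpha / m:
            kmax = rank
    return {order[i] for i in range(kmax)}


def topology_stats(edges: set, nodes: list) -> dict:
    """Node/edge counts, components, diameter/CPL on the largest component,
    mean local clustering over degree->=2 nodes."""
    dist, _, _ = shortest_path_profile(edges, nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, stack = {start}, [start]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        comps.append(comp)
    big = max(comps, key=lambda c: (len(c), str(sorted(map(str, c))[0])))
    if len(big) > 1:
        pairs = list(itertools.combinations(sorted(big, key=str), 2))
        ds = [dist[a][b] for a, b in pairs]
        diameter, cpl = max(ds), sum(ds) / len(ds)
    else:
        diameter, cpl = 0, 0.0
    cc = []
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(adj[v], key=str), 2)
            if b in adj[a]
        )
        cc.append(2.0 * links / (k * (k - 1)))
    return {
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "n_components": len(comps),
        "diameter": diameter,
        "char_path_length": cpl,
        "clustering": sum(cc) / len(cc) if cc else 0.0,
    }
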