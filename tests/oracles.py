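"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: cubic all-pairs distances, exhaustive shortest-path
enumeration, dense eigendecomposition, union-find.  None of them share code
with the package under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def floyd_warshall(g) -> dict[str, dict[str, float]]:
    nodes = g.nodes
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for v in nodes:
        dist[v][v] = 0
    for u, v in g.edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik is math.inf:
                continue
            for j in nodes:
                if dik + dist[k][j] < dist[i][j]:
                    dist[i][j] = dik + dist[k][j]
    return dist


def enumerate_shortest_paths(g, s: str, t: str, dist=None) -> list[tuple[str, ...]]:
    """All shortest s-t paths by DFS, pruned by exact distances."""
    if dist is None:
        dist = floyd_warshall(g)
    target_len = dist[s][t]
    if math.isinf(target_len):
        return []
    paths: list[tuple[str, ...]] = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        for w in g.neighbors(v):
            if dist[s][v] + 1 + dist[w][t] == target_len and dist[s][w] == dist[s][v] + 1:
                extend(path + [w])

    extend([s])
    return paths


def brute_betweenness(g) -> dict[str, float]:
    """Direct evaluation: sum over unordered pairs of the fraction of
    shortest paths using v as an interior node."""
    dist = floyd_warshall(g)
    bc = {v: 0.0 for v in g.nodes}
    for s, t in combinations(g.nodes, 2):
        paths = enumerate_shortest_paths(g, s, t, dist)
        if not paths:
            continue
        total = len(paths)
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / total
    return bc


def largest_component_nodes(g) -> set[str]:
    comps = union_find_components(g)
    mx = max(len(c) for c in comps)
    return min((c for c in comps if len(c) == mx), key=min)


def brute_closeness(g) -> dict[str, float]:
    """1/farness on the largest component (components found by union-find)."""
    sub = g.subgraph(largest_component_nodes(g))
    dist = floyd_warshall(sub)
    return {v: 1.0 / sum(dist[v][t] for t in sub.nodes) for v in sub.nodes}


def brute_eccentricity(g) -> dict[str, float]:
    sub = g.subgraph(largest_component_nodes(g))
    dist = floyd_warshall(sub)
    return {v: float(max(dist[v][t] for t in sub.nodes)) for v in sub.nodes}


def dense_eigenvector(g) -> tuple[float, dict[str, float]]:
    """Dominant eigenpair from a full symmetric eigendecomposition."""
    nodes = g.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    w, vecs = np.linalg.eigh(a)
    lead = vecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    return float(w[-1]), {v: float(lead[idx[v]]) for v in nodes}


def union_find_components(g) -> list[set[str]]:
    parent = {v: v for v in g.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in g.edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[str, set[str]] = {}
    for v in g.nodes:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())
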