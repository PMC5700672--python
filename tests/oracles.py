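"""Independent brute-force oracles used to validate the package's operations.

Everything here is deliberately naive: path enumeration by DFS, confusion
matrices by explicit set algebra, independent sets by exact solvers on tiny
graphs.  None of it shares code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def enumerate_simple_paths(G: nx.Graph, s: str, t: str) -> list[list[str]]:
    """All simple s-t paths by explicit DFS."""
    paths: list[list[str]] = []

    def walk(node, visited, path):
        if node == t:
            paths.append(path[:])
            return
        for nxt in G[node]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                walk(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    walk(s, {s}, [s])
    return paths


def brute_betweenness(G: nx.Graph) -> dict[str, float]:
    """Normalized betweenness by enumerating every shortest path."""
    nodes = list(G.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_simple_paths(G, s, t)
        if not paths:
            continue  # disconnected pair contributes nothing
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in shortest)
            raw[v] += through / len(shortest)
    if n < 3:
        return dict.fromkeys(nodes, 0.0)
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in nodes}


def bfs_distances(G: nx.Graph, source: str) -> dict[str, int]:
    """Plain hand-rolled BFS."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def confusion_sweep_auroc(ranking: list[str], gold: set[str], universe: set[str]) -> float:
    """AUROC from explicit per-rank confusion matrices + trapezoid."""
    pos = gold & universe
    neg = universe - pos
    pts = [(0.0, 0.0)]
    for size in range(1, len(ranking) + 1):
        head = set(ranking[:size])
        tp = len(head & pos)
        fp = len(head & neg)
        pts.append((fp / len(neg) if neg else 0.0, tp / len(pos)))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def exact_mwis_weight(G: nx.Graph, weights: dict[str, float]) -> float:
    """Exact maximum-weight independent set weight by subset enumeration
    (graphs of up to ~15 nodes)."""
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in G.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    best = 0.0
    for mask in range(1 << n):
        total = 0.0
        ok = True
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if adj[i] & mask:
                ok = False
                break
            total += weights[nodes[i]]
            m &= m - 1
        if ok and total > best:
            best = total
    return best


def lazy_walk_stationary(G: nx.Graph) -> dict[str, float]:
    """Closed-form stationary distribution of the lazy walk: pi(v) ~ deg(v)+1."""
    z = sum(G.degree(v) + 1 for v in G.nodes)
    return {v: (G.degree(v) + 1) / z for v in G.nodes}
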