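"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and networkx's
Brandes/BFS implementations): shortest paths are found by exhaustive
simple-path enumeration, so they are only usable on tiny graphs.
"""

from __future__ import annotations

import itertools


def _all_simple_paths(adj: dict, s, t) -> list[tuple]:
    """Every simple s-t path, by plain DFS over an adjacency dict."""
    paths, stack = [], [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + (nb,)))
    return paths


def shortest_paths_by_enumeration(edges, nodes):
    """dict (s, t) -> list of shortest paths, for every unordered pair."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        out[(s, t)] = [p for p in paths if len(p) == d]
    return out


def brute_force_centralities(edges, nodes):
    """(betweenness, closeness, degree) dicts from path enumeration.

    Betweenness is normalized by (n-1)(n-2)/2; closeness is
    (n-1)/sum-of-distances.  Assumes a connected graph.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    sp = shortest_paths_by_enumeration(edges, nodes)
    bc = {v: 0.0 for v in nodes}
    dist = {v: 0 for v in nodes}
    for (s, t), paths in sp.items():
        d = len(paths[0]) - 1
        dist[s] += d
        dist[t] += d
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return (
        {v: bc[v] / norm for v in nodes},
        {v: (n - 1) / dist[v] if dist[v] else 0.0 for v in nodes},
        deg,
    )
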