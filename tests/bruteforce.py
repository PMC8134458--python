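"""Independent brute-force oracles for graph metrics and FDR.

Deliberately naive (pure-Python enumeration, Floyd–Warshall, exhaustive
shortest-path listing) so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

INF = math.inf


def bf_distances(adj):
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_clustering(adj):
    n = len(adj)
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nbrs[a]][nbrs[b]]
        )
        vals.append(2.0 * links / (k * (k - 1)))
    return sum(vals) / n


def bf_lp(adj):
    d = bf_distances(adj)
    n = len(adj)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    return sum(finite) / len(finite) if finite else float("nan")


def bf_eglob(adj):
    d = bf_distances(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF
    )
    return total / (n * (n - 1))


def bf_eloc(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        total += bf_eglob(sub)
    return total / n


def bf_nodal_efficiency(adj):
    d = bf_distances(adj)
    n = len(adj)
    return [
        sum(1.0 / d[i][j] for j in range(n) if j != i and d[i][j] < INF) / (n - 1)
        for i in range(n)
    ]


def _all_shortest_paths(adj, s, t, d):
    """All paths from s to t of exactly the shortest length (DFS)."""
    target_len = d[s][t]
    if target_len == INF:
        return []
    n = len(adj)
    out, stack = [], [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t and len(path) - 1 == target_len:
            out.append(path)
            continue
        if len(path) - 1 >= target_len:
            continue
        for nxt in range(n):
            if adj[node][nxt] and nxt not in path:
                # prune branches that can no longer reach t within the
                # shortest length: edges so far after stepping to nxt is
                # len(path), plus at least d[nxt][t] more
                if d[nxt][t] == INF or len(path) + d[nxt][t] > target_len:
                    continue
                stack.append((nxt, path + [nxt]))
    return out


def bf_betweenness(adj):
    """Unnormalized shortest-path betweenness, each unordered pair once."""
    n = len(adj)
    d = bf_distances(adj)
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, d)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                bc[v] += through / len(paths)
    return bc


def bf_fdr(p):
    """Benjamini–Hochberg step-up by direct definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def random_adj(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return (a | a.T).astype(bool)
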