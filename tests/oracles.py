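"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: centralities
are computed by naive all-pairs BFS path enumeration, and hypergeometric
tails by exact integer combinatorics.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction


def bfs_distances(adj: dict, source) -> dict:
    """Hop distances from source over an adjacency mapping."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_adj(graph) -> dict:
    return {n: sorted(graph.neighbors(n)) for n in graph.nodes}


def oracle_degree(graph) -> dict:
    adj = graph_adj(graph)
    return {n: len(adj[n]) for n in adj}


def oracle_closeness(graph) -> dict:
    """Component-scaled closeness from BFS distances:
    cc(v) = ((s-1)/(n-1)) * ((s-1)/sum_d) with s the size of v's component."""
    adj = graph_adj(graph)
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        s = len(dist)
        tot = sum(dist.values())
        if s <= 1 or n <= 1 or tot == 0:
            out[v] = 0.0
        else:
            out[v] = ((s - 1) / (n - 1)) * ((s - 1) / tot)
    return out


def oracle_betweenness(graph, normalized: bool = False) -> dict:
    """Betweenness by explicit shortest-path counting.

    For every ordered pair (s, t), count geodesics sigma_st and the number
    sigma_st(v) passing through each intermediate v (dynamic programming on
    BFS layers), then sum sigma_st(v)/sigma_st over unordered pairs.
    """
    adj = graph_adj(graph)
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s = bfs_distances(adj, s)
        # geodesic counts from s
        sigma_s = _path_counts(adj, s, dist_s)
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            d = dist_s[t]
            dist_t = bfs_distances(adj, t)
            sigma_t = _path_counts(adj, t, dist_t)
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    bc[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: x * scale for v, x in bc.items()}
    return bc


def _path_counts(adj, source, dist) -> dict:
    counts = {source: 1}
    for v in sorted(dist, key=dist.get):
        if v == source:
            continue
        counts[v] = sum(counts[u] for u in adj[v] if u in dist and dist[u] == dist[v] - 1)
    return counts


def oracle_hypergeom_upper(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact rational P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    total = math.comb(N, K)  # condition on which genes are in the term
    tail = sum(math.comb(n, j) * math.comb(N - n, K - j) for j in range(k, min(K, n) + 1))
    return Fraction(tail, total)


def oracle_bh(pvals):
    """BH step-up by its textbook definition: adj_(i) = min over j >= i of
    min(1, m * p_(j) / j), mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        adj_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out
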