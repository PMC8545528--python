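"""Independent brute-force oracles used only by the tests.

Deliberately naive algorithms (BFS path enumeration, repeated peeling,
combinatorial enumeration) kept separate from the package implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s-t path, by BFS levels + recursive backtracking."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    if t not in dist:
        return []
    paths = []

    def back(node, suffix):
        if node == s:
            paths.append([s] + suffix)
            return
        for u in adj[node]:
            if dist.get(u, math.inf) == dist[node] - 1:
                back(u, [node] + suffix)

    back(t, [])
    return paths


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by explicit shortest-path enumeration."""
    nodes = sorted(graph.nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    scale = (n - 1) * (n - 2) / 2
    return {v: raw[v] / scale for v in nodes}


def brute_intermediate_total(graph) -> float:
    """Total (unnormalized) intermediate-node weight over shortest paths."""
    nodes = sorted(graph.nodes)
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    total = 0.0
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            total += sum(1 for p in paths if v in p) / len(paths)
    return total


def brute_core_numbers(graph) -> dict:
    """core(v) = max k such that v survives deleting degree<k to fixpoint."""
    import networkx as nx

    core = {v: 0 for v in graph.nodes}
    for k in range(1, graph.number_of_nodes() + 1):
        g = nx.Graph(graph)
        while True:
            low = [v for v in g.nodes if g.degree(v) < k]
            if not low:
                break
            g.remove_nodes_from(low)
        for v in g.nodes:
            core[v] = k
    return core


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)

    def u_stat(group1, group2):
        return sum(1 for a in group1 for b in group2 if a > b)

    u_obs = u_stat(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_stat(g1, g2))
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def hypergeom_upper_p(n_universe, n_set, n_query, overlap) -> float:
    """P(X >= overlap) by direct combinatorial summation."""
    total = math.comb(n_universe, n_query)
    acc = 0
    for k in range(overlap, min(n_set, n_query) + 1):
        acc += math.comb(n_set, k) * math.comb(n_universe - n_set, n_query - k)
    return acc / total


def bh_adjust_direct(pvals) -> list:
    """BH: p * m / rank with right-to-left monotonicity, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(pvals[i] * m / (rank_idx + 1), prev)
        adj[i] = val
        prev = val
    return adj
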