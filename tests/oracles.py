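"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — subset enumeration, path
enumeration, draw enumeration — and shares no code with the package's
implementations.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_maximal_cliques(nodes: list, edge_set: set[frozenset]) -> set[frozenset]:
    """All maximal cliques of size >= 2 by enumerating every node subset."""

    def is_clique(subset):
        return all(frozenset(p) in edge_set for p in combinations(subset, 2))

    cliques = [
        frozenset(s)
        for r in range(2, len(nodes) + 1)
        for s in combinations(nodes, r)
        if is_clique(s)
    ]
    return {
        c for c in cliques if not any(c < other for other in cliques)
    }


def brute_mcc(nodes: list, edge_set: set[frozenset]) -> dict:
    """MCC by direct summation over the enumerated maximal cliques."""
    cliques = brute_maximal_cliques(nodes, edge_set)
    out = {v: 0 for v in nodes}
    for c in cliques:
        contrib = math.factorial(len(c) - 1)
        for v in c:
            out[v] += contrib
    return out


def brute_betweenness(nodes: list, edge_set: set[frozenset]) -> dict:
    """Unnormalized betweenness by enumerating every simple path.

    For each ordered source/target pair, all simple paths are enumerated by
    depth-first search; shortest ones are kept and interior vertices
    credited with the fraction of shortest paths passing through them.
    Undirected pairs counted once.
    """
    adj = {v: set() for v in nodes}
    for e in edge_set:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


def brute_hypergeom_upper(M: int, K: int, n: int, k: int) -> float:
    """Pr(X >= k) by enumerating every n-draw from an M-item universe."""
    items = list(range(M))  # first K items carry the annotation
    hits = 0
    total = 0
    for draw in combinations(items, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


def brute_combined_score(channel_scores, prior: float) -> float:
    """Direct evaluation of the prior-corrected probabilistic combination."""
    corrected = []
    for s in channel_scores:
        c = (s - prior) / (1 - prior)
        corrected.append(c if c > 0 else 0.0)
    if max(corrected, default=0.0) == 0.0:
        return 0.0
    prod = 1.0
    for c in corrected:
        prod *= 1.0 - c
    return (1.0 - prod) * (1.0 - prior) + prior


def enumerate_internal_edge_expectation(
    nodes: list, degree: dict, module: set
) -> float:
    """Mean module-internal edge count over ALL simple graphs with the
    given degree sequence, by brute force over edge subsets."""
    pairs = list(combinations(nodes, 2))
    total_graphs = 0
    total_internal = 0
    target = sum(degree.values()) // 2
    for edges in combinations(pairs, target):
        deg = {v: 0 for v in nodes}
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        if deg == degree:
            total_graphs += 1
            total_internal += sum(
                1 for a, b in edges if a in module and b in module
            )
    return total_internal / total_graphs
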