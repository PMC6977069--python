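"""Independent brute-force oracles for the graph and statistics routines.

Everything here is deliberately naive — union-find, exhaustive path
enumeration, exact rational arithmetic, full permutation enumeration —
and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def uf_components(nodes, edges) -> int:
    """Connected components over non-isolated nodes via union-find."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    touched = set()
    for a, b in edges:
        touched.update((a, b))
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(x) for x in touched})


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency(nodes, edges) -> dict:
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def max_component_diameters(nodes, edges) -> set[int]:
    """Diameters of every maximum-size component (candidates for ties)."""
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        comp = set(bfs_distances(adj, n))
        seen |= comp
        comps.append(comp)
    size = max(len(c) for c in comps)
    out = set()
    for comp in comps:
        if len(comp) != size:
            continue
        ecc = [max(bfs_distances(adj, n).values()) for n in comp]
        out.add(max(ecc) if ecc else 0)
    return out


def brute_betweenness(nodes, edges) -> dict:
    """Betweenness by enumerating every simple path between every pair."""
    nodes = list(nodes)
    adj = adjacency(nodes, edges)
    bc = {n: 0.0 for n in nodes}
    n = len(nodes)

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                yield path
                continue
            for v in adj[u]:
                if v not in path:
                    stack.append((v, path + [v]))

    for s, t in itertools.combinations(nodes, 2):
        paths = list(simple_paths(s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        bc = {v: x / norm for v, x in bc.items()}
    return bc


def density_oracle(n_nodes: int, edges) -> float:
    return 2.0 * len(set(frozenset(e) for e in edges)) / (n_nodes * (n_nodes - 1))


def centralization_oracle(nodes, edges) -> float:
    adj = adjacency(nodes, edges)
    degs = [len(adj[n]) for n in nodes]
    n = len(nodes)
    return sum(max(degs) - d for d in degs) / ((n - 1) * (n - 2))


def exact_binom_upper_tail(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p) in exact rational arithmetic."""
    return sum(
        Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def spearman_oracle(x, y) -> tuple[float, float]:
    """Spearman rho and exact two-sided permutation p by full enumeration."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for idx in order[i : j + 1]:
                r[idx] = avg
            i = j + 1
        return r

    def rho_of(rx, ry):
        n = len(rx)
        mx = sum(rx) / n
        my = sum(ry) / n
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = (
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        ) ** 0.5
        return num / den

    rx, ry = ranks(list(x)), ranks(list(y))
    rho = rho_of(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total
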