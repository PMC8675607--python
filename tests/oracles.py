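"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written in the most literal way possible
(triple loops, explicit BFS, full ratio matrices) and shares no code with
the package.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def bf_size_factors(counts: np.ndarray) -> np.ndarray:
    """Literal median-of-ratios: full ratio matrix, column medians."""
    positive = (counts > 0).all(axis=1)
    ref = counts[positive].astype(float)
    geo = np.exp(np.log(ref).mean(axis=1))
    ratio = ref / geo[:, None]
    return np.median(ratio, axis=0)


def bf_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def _bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _components(adj: dict) -> list[set]:
    seen, comps = set(), []
    for v in adj:
        if v not in seen:
            comp = set(_bfs_distances(adj, v))
            seen |= comp
            comps.append(comp)
    return comps


def _count_shortest_paths(adj: dict, s):
    """BFS path counting; returns (dist, number of shortest paths, predecessors)."""
    dist = {s: 0}
    sigma = {s: 1}
    preds: dict = {v: [] for v in adj}
    q = deque([s])
    order = []
    while q:
        u = q.popleft()
        order.append(u)
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def bf_centralities(edges, nodes) -> dict:
    """Degree, betweenness, closeness, clustering from first principles.

    Betweenness sums sigma_st(v)/sigma_st over all unordered pairs s < t of
    v's component and divides by (N-1)(N-2)/2 with N the component size;
    closeness is 1 / mean BFS distance to the other component members;
    clustering counts connected neighbour pairs.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    deg = {v: len(adj[v]) for v in nodes}

    cc = {}
    for v in nodes:
        k = deg[v]
        if k < 2:
            cc[v] = 0.0
        else:
            e = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
            cc[v] = 2.0 * e / (k * (k - 1))

    comps = _components(adj)
    comp_of = {}
    for comp in comps:
        for v in comp:
            comp_of[v] = comp

    cn = {}
    for v in nodes:
        comp = comp_of[v]
        if len(comp) == 1:
            cn[v] = 0.0
        else:
            d = _bfs_distances(adj, v)
            cn[v] = (len(comp) - 1) / sum(d[u] for u in comp if u != v)

    bw = {v: 0.0 for v in nodes}
    for comp in comps:
        if len(comp) < 3:
            continue
        raw = {v: 0.0 for v in comp}
        members = sorted(comp)
        for s, t in combinations(members, 2):
            dist, sigma, preds, _ = _count_shortest_paths(adj, s)
            # walk the predecessor DAG from t back to s; paths_to[v] = number
            # of shortest v->t path continuations
            paths_to = {t: 1}
            order = sorted(
                (v for v in comp if v in dist and dist[v] <= dist.get(t, 0)),
                key=lambda v: -dist[v],
            )
            for v in order:
                if v not in paths_to:
                    continue
                for p in preds[v]:
                    paths_to[p] = paths_to.get(p, 0) + paths_to[v]
            for v in comp:
                if v in (s, t) or v not in paths_to or v not in dist:
                    continue
                # paths through v = sigma(s->v) * paths from v to t
                raw[v] += sigma.get(v, 0) * paths_to[v] / sigma[t]
        n = len(comp)
        norm = (n - 1) * (n - 2) / 2.0
        for v in comp:
            bw[v] = raw[v] / norm
    return {"DG": deg, "BW": bw, "CN": cn, "CC": cc}


def bf_hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    total = comb(big_n, n)
    return sum(
        comb(big_k, i) * comb(big_n - big_k, n - i)
        for i in range(k, min(big_k, n) + 1)
    ) / total


def bf_bh(p: list[float]) -> list[float]:
    """Step-up BH by the definition q_(i) = min_{j>=i} (m/j) p_(j), capped."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q
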