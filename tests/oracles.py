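"""Independent brute-force implementations used only as test oracles.

Everything here is written from the definitions (path enumeration,
triangle counting, exhaustive partition scans) without using the package
or networkx, so that agreement with the fast implementations is a real
cross-check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

INF = float("inf")


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.where(a > 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nodal_path_length(a: np.ndarray) -> np.ndarray:
    d = floyd_warshall(a)
    n = a.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and d[i, j] < INF]
        if vals:
            out[i] = sum(vals) / len(vals)
    return out


def nodal_efficiency(a: np.ndarray) -> np.ndarray:
    d = floyd_warshall(a)
    n = a.shape[0]
    return np.array(
        [sum(1.0 / d[i, j] for j in range(n) if j != i and d[i, j] < INF) / (n - 1)
         for i in range(n)]
    )


def clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(a[u, v] for u, v in combinations(nbrs, 2))
        out[i] = 2 * tri / (k * (k - 1))
    return out


def _count_shortest_paths(a: np.ndarray, d: np.ndarray, s: int, t: int):
    """All shortest s→t paths by DFS along the BFS distance gradient."""
    if d[s, t] == INF or s == t:
        return []
    n = a.shape[0]
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in range(n):
            if a[node, nxt] and d[nxt, t] == d[node, t] - 1:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return paths


def betweenness(a: np.ndarray) -> np.ndarray:
    """Normalized betweenness: fraction of shortest paths through i,
    averaged over the (n-1)(n-2) ordered pairs excluding i."""
    n = a.shape[0]
    d = floyd_warshall(a)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i or d[h, j] == INF:
                    continue
                paths = _count_shortest_paths(a, d, h, j)
                through = sum(1 for p in paths if i in p)
                acc += through / len(paths)
        out[i] = acc / ((n - 1) * (n - 2))
    return out


def participation(a: np.ndarray, modules: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(modules):
            km = sum(a[i, j] for j in range(n) if modules[j] == m)
            acc += (km / k) ** 2
        out[i] = 1.0 - acc
    return out


def assortativity(a: np.ndarray) -> float:
    """Literal evaluation of the degree-correlation formula over links."""
    k = a.sum(axis=1)
    links = [(i, j) for i in range(a.shape[0]) for j in range(i + 1, a.shape[0])
             if a[i, j]]
    if len(links) < 2:
        return float("nan")
    inv = 1.0 / len(links)
    s_prod = inv * sum(k[i] * k[j] for i, j in links)
    s_mean = inv * sum(0.5 * (k[i] + k[j]) for i, j in links)
    s_sq = inv * sum(0.5 * (k[i] ** 2 + k[j] ** 2) for i, j in links)
    den = s_sq - s_mean**2
    if abs(den) < 1e-14:
        return float("nan")
    return (s_prod - s_mean**2) / den


def synchronization(a: np.ndarray) -> float:
    lap = np.diag(a.sum(axis=1)) - a.astype(float)
    vals = np.sort(np.linalg.eigvalsh(lap))
    return max(vals[1], 0.0) / vals[-1] if vals[-1] > 0 else 0.0


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    def rec(i, labels, k):
        if i == n:
            yield np.array(labels)
            return
        for c in range(k + 1):
            yield from rec(i + 1, labels + [c], max(k, c + 1))

    yield from rec(0, [], 0)


def modularity_value(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Plain double-sum Newman-Girvan modularity (self pairs included)."""
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


_ONEHOT_CACHE: dict[int, np.ndarray] = {}


def all_partition_onehots(n: int) -> np.ndarray:
    """(n_partitions, n, n) one-hot membership stacks, cached per n."""
    if n not in _ONEHOT_CACHE:
        parts = list(set_partitions(n))
        o = np.zeros((len(parts), n, n))
        for p, labels in enumerate(parts):
            o[p, np.arange(n), labels] = 1.0
        _ONEHOT_CACHE[n] = o
    return _ONEHOT_CACHE[n]


def max_modularity(w: np.ndarray, gamma: float = 1.0) -> float:
    """Exhaustive scan over all partitions (n <= 8)."""
    n = w.shape[0]
    assert n <= 8, "exhaustive scan limited to 8 nodes"
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    b = w - gamma * np.outer(k, k) / two_m
    o = all_partition_onehots(n)
    q = np.einsum("pic,ij,pjc->p", o, b, o)
    return float(q.max() / two_m)


def trapezoid(xs, ys) -> float:
    acc = 0.0
    for k in range(1, len(xs)):
        acc += 0.5 * (ys[k] + ys[k - 1]) * (xs[k] - xs[k - 1])
    return acc


def random_connected_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Rejection-sample a connected simple graph adjacency."""
    while True:
        a = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    a[i, j] = a[j, i] = 1
        # connectivity by label propagation
        seen = {0}
        frontier = [0]
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if a[u, v] and v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if len(seen) == n:
            return a
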