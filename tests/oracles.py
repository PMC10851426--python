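"""Exhaustive reference implementations for small graphs.

Everything here is deliberately naive — pure-Python BFS, triple
enumeration for triangles, explicit enumeration of all shortest paths for
betweenness — and shares no code with the package. Only usable for graphs
of a few dozen nodes.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj):
    """All-pairs shortest-path lengths by per-source queue BFS."""
    A = np.asarray(adj).astype(bool)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(A[u]):
                if np.isinf(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def clustering(adj):
    """Per-node clustering by enumerating all neighbor pairs."""
    A = np.asarray(adj).astype(bool)
    n = A.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if nb.size < 2:
            continue
        links = sum(1 for u, v in combinations(nb, 2) if A[u, v])
        c[i] = 2.0 * links / (nb.size * (nb.size - 1))
    return c.mean(), c


def characteristic_path_length(adj):
    D = bfs_distances(adj)
    vals = [
        D[i, j]
        for i in range(D.shape[0])
        for j in range(D.shape[0])
        if i != j and np.isfinite(D[i, j])
    ]
    if not vals:
        raise ValueError("no finite pairs")
    return float(np.mean(vals))


def global_efficiency(adj):
    D = bfs_distances(adj)
    n = D.shape[0]
    if n < 2:
        return 0.0
    vals = [
        1.0 / D[i, j] if np.isfinite(D[i, j]) else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def nodal_efficiency(adj):
    D = bfs_distances(adj)
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / D[i, j] if np.isfinite(D[i, j]) else 0.0
            for j in range(n)
            if j != i
        ) / (n - 1)
    return out


def local_efficiency(adj):
    A = np.asarray(adj).astype(bool)
    n = A.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if nb.size >= 2:
            e[i] = global_efficiency(A[np.ix_(nb, nb)])
    return e.mean(), e


def _all_shortest_paths(adj, D, s, t):
    """Every shortest s->t path, by DFS over the BFS-distance DAG."""
    A = np.asarray(adj).astype(bool)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in np.flatnonzero(A[u]):
            if D[s, v] == D[s, u] + 1 and D[v, t] == D[u, t] - 1:
                extend(path + [v])

    if np.isfinite(D[s, t]):
        extend([s])
    return paths


def betweenness(adj):
    """Unnormalized betweenness by enumerating all shortest paths of every
    unordered pair and crediting interior nodes fractionally."""
    A = np.asarray(adj).astype(bool)
    n = A.shape[0]
    D = bfs_distances(A)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(A, D, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for node in path[1:-1]:
                bc[node] += w
    return bc


def trapezoid(values, xs):
    """Sum of per-interval trapezoids, accumulated independently."""
    total = 0.0
    for k in range(len(xs) - 1):
        total += 0.5 * (values[k] + values[k + 1]) * (xs[k + 1] - xs[k])
    return total
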