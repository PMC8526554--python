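"""Independent brute-force reference implementations used only by tests.

Everything here is written from the defining formulas with plain loops, on
purpose — no shared code with the package, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list:
    """Single-source shortest-path lengths by breadth-first search."""
    n = adj.shape[0]
    dist = [None] * n
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] is None:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def global_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        dist = bfs_distances(adj, i)
        for j in range(n):
            if i != j and dist[j] is not None:
                total += 1.0 / dist[j]
    return total / (n * (n - 1))


def assortativity_brute(adj: np.ndarray) -> float:
    """Pearson correlation of end-point degrees over directed edge list."""
    n = adj.shape[0]
    deg = [int(adj[i].sum()) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    sx = xs.std()
    sy = ys.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))


def clustering_brute(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def _count_shortest_paths(adj: np.ndarray, s: int, t: int, d: int):
    """All shortest s-t paths by depth-limited DFS; returns (count, interior
    visit counts per node)."""
    n = adj.shape[0]
    interior = np.zeros(n)
    count = 0
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            if len(path) - 1 == d:
                count += 1
                for v in path[1:-1]:
                    interior[v] += 1
            continue
        if len(path) - 1 >= d:
            continue
        for v in range(n):
            if adj[u, v] and v not in path:
                stack.append((v, path + [v]))
    return count, interior


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(s + 1, n):
            if dist[t] is None:
                continue
            n_paths, interior = _count_shortest_paths(adj, s, t, dist[t])
            if n_paths:
                bc += interior / n_paths
    return bc / ((n - 1) * (n - 2) / 2.0)


def taper_brute(w: int, sigma: float) -> np.ndarray:
    """Rectangle * truncated-Gaussian discrete convolution by double loop."""
    half = int(np.ceil(3 * sigma))
    support = list(range(-half, half + 1))
    kernel = [np.exp(-0.5 * (s / sigma) ** 2) for s in support]
    ksum = sum(kernel)
    kernel = [v / ksum for v in kernel]
    rect = [1.0] * w
    full = [0.0] * (w + 2 * half)
    for i in range(w):
        for j, kv in enumerate(kernel):
            full[i + j] += rect[i] * kv
    central = full[half : half + w]
    total = sum(central)
    return np.array([v / total for v in central])


def partial_corr_brute(x, y, z) -> float:
    """Two-stage residualize-then-correlate with explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    design = np.column_stack([np.ones(n), np.asarray(z, float)])
    gram = design.T @ design
    rx = x - design @ np.linalg.solve(gram, design.T @ x)
    ry = y - design @ np.linalg.solve(gram, design.T @ y)
    return float(np.corrcoef(rx, ry)[0, 1])


def bh_adjust_brute(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[r - 1]] * m / r for r in range(rank, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


def markov_stationary(stay1: float, stay2: float) -> tuple[float, float]:
    """Closed-form stationary distribution of the 2-state chain."""
    a, b = 1 - stay1, 1 - stay2
    return b / (a + b), a / (a + b)


def sample_variance_brute(values) -> float:
    v = list(values)
    mean = sum(v) / len(v)
    return sum((x - mean) ** 2 for x in v) / (len(v) - 1)


def random_binary_graph(n: int, density: float, rng) -> np.ndarray:
    adj = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < density:
            adj[i, j] = adj[j, i] = 1
    return adj
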