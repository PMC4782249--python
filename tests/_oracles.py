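"""Independent brute-force oracles for graph metrics and curve distances.

Everything here is written from first principles (explicit Floyd-Warshall,
triangle enumeration, shortest-path counting, exhaustive coupling search)
and deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

INF = np.inf


def length_matrix(adj: np.ndarray, weighted: bool) -> np.ndarray:
    """Edge-length matrix: 1 for binary edges, 1/w for weighted ones."""
    n = adj.shape[0]
    lengths = np.full((n, n), INF)
    for i in range(n):
        lengths[i, i] = 0.0
        for j in range(n):
            if i != j and adj[i, j] > 0:
                lengths[i, j] = 1.0 / adj[i, j] if weighted else 1.0
    return lengths


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(d: np.ndarray) -> float:
    """Mean shortest-path length over connected off-diagonal pairs."""
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def global_efficiency(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j]) and d[i, j] > 0
    )
    return total / (n * (n - 1))


def nodal_efficiency(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def clustering_binary(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    a = (adj > 0).astype(int)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[u, v] for ui, u in enumerate(nbrs) for v in nbrs[ui + 1:])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def clustering_onnela(adj: np.ndarray) -> np.ndarray:
    """Weighted clustering: geometric mean of triangle weights, normalized
    by the maximum weight in the graph (Onnela form)."""
    n = adj.shape[0]
    wmax = adj.max()
    if wmax <= 0:
        return np.zeros(n)
    what = adj / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for ui, u in enumerate(nbrs):
            for v in nbrs[ui + 1:]:
                if adj[u, v] > 0:
                    acc += (what[i, u] * what[i, v] * what[u, v]) ** (1.0 / 3.0)
        out[i] = 2.0 * acc / (k * (k - 1))
    return out


def local_efficiency(adj: np.ndarray, weighted: bool) -> float:
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = global_efficiency(floyd_warshall(length_matrix(sub, weighted)))
    return float(vals.mean())


def _path_counts(lengths: np.ndarray, d: np.ndarray, s: int, rtol: float = 1e-9) -> np.ndarray:
    """Number of shortest paths from s to every node, by DP in distance order."""
    n = lengths.shape[0]
    sigma = np.zeros(n)
    sigma[s] = 1.0
    order = np.argsort(d[s])
    for v in order:
        if v == s or not np.isfinite(d[s, v]):
            continue
        for u in range(n):
            if u != v and np.isfinite(lengths[u, v]) and np.isfinite(d[s, u]):
                if np.isclose(d[s, u] + lengths[u, v], d[s, v], rtol=rtol, atol=1e-12):
                    sigma[v] += sigma[u]
    return sigma


def betweenness(adj: np.ndarray, weighted: bool) -> np.ndarray:
    """Unnormalized betweenness: each unordered pair (s, t) contributes
    sigma_sv * sigma_vt / sigma_st to every intermediate v on a shortest
    path."""
    n = adj.shape[0]
    lengths = length_matrix(adj, weighted)
    d = floyd_warshall(lengths)
    sigma = np.array([_path_counts(lengths, d, s) for s in range(n)])
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if np.isclose(d[s, v] + d[v, t], d[s, t], rtol=1e-9, atol=1e-12):
                    out[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return out


def frechet_exhaustive(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum over all monotone couplings of the max pointwise distance,
    by explicit enumeration of lattice paths (curves of length <= ~6)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    p, q = len(a), len(b)
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    best = [INF]

    def walk(i: int, j: int, cur: float) -> None:
        cur = max(cur, dist[i, j])
        if cur >= best[0]:
            return
        if i == p - 1 and j == q - 1:
            best[0] = cur
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < p and nj < q:
                walk(ni, nj, cur)

    walk(0, 0, 0.0)
    return float(best[0])
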