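"""Brute-force graph-metric oracles via exhaustive simple-path enumeration.

Deliberately independent of the package implementation: distances come from
enumerating every simple path, betweenness from counting shortest paths
directly, clustering from explicit triangle loops.  Only feasible for tiny
graphs (<= ~8 nodes), which is the point.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-9


def _lengths(A: np.ndarray, weighted: bool) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, (1.0 / A) if weighted else 1.0, np.inf)
    np.fill_diagonal(L, np.inf)
    return L


def all_shortest_paths(A: np.ndarray, weighted: bool
                       ) -> dict[tuple[int, int], tuple[float, list[list[int]]]]:
    n = A.shape[0]
    L = _lengths(A, weighted)
    out: dict[tuple[int, int], tuple[float, list[list[int]]]] = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                out[(s, t)] = (0.0, [[s]])
                continue
            best = np.inf
            paths: list[list[int]] = []
            stack = [([s], 0.0)]
            while stack:
                path, d = stack.pop()
                u = path[-1]
                for v in range(n):
                    if not np.isfinite(L[u, v]) or v in path:
                        continue
                    nd = d + L[u, v]
                    if nd > best + _TOL:
                        continue
                    if v == t:
                        if nd < best - _TOL:
                            best = nd
                            paths = [path + [v]]
                        else:
                            paths.append(path + [v])
                    else:
                        stack.append((path + [v], nd))
            # drop stale paths that were tied with a later-improved best
            paths = [p for p in paths
                     if abs(sum(L[a, b] for a, b in zip(p, p[1:])) - best) <= _TOL]
            out[(s, t)] = (best, paths)
    return out


def bf_distances(A: np.ndarray, weighted: bool) -> np.ndarray:
    sp = all_shortest_paths(A, weighted)
    n = A.shape[0]
    D = np.zeros((n, n))
    for (s, t), (d, _) in sp.items():
        D[s, t] = d
    return D


def bf_global_efficiency(A: np.ndarray, weighted: bool) -> np.ndarray:
    D = bf_distances(A, weighted)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
        out[i] = acc / (n - 1)
    return out


def bf_local_efficiency(A: np.ndarray, weighted: bool) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        out[i] = bf_global_efficiency(sub, weighted).mean()
    return out


def bf_clustering(A: np.ndarray, weighted: bool) -> np.ndarray:
    n = A.shape[0]
    k = (A > 0).sum(axis=1)
    W = np.cbrt(A / A.max()) if (weighted and A.max() > 0) else (A > 0).astype(float)
    out = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        acc = 0.0
        for j in range(n):
            for l in range(n):
                acc += W[i, j] * W[j, l] * W[l, i]
        out[i] = acc / (k[i] * (k[i] - 1))
    return out


def bf_betweenness(A: np.ndarray, weighted: bool, normalized: bool = True
                   ) -> np.ndarray:
    n = A.shape[0]
    sp = all_shortest_paths(A, weighted)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            dist, paths = sp[(s, t)]
            if not np.isfinite(dist) or not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def random_symmetric_graph(rng: np.random.Generator, n: int, weighted: bool,
                           p: float = 0.5) -> np.ndarray:
    """Random undirected graph; weights in [0.2, 1] to keep path sums tame."""
    A = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p
    vals = rng.uniform(0.2, 1.0, size=len(iu[0])) if weighted else np.ones(len(iu[0]))
    A[iu] = np.where(mask, vals, 0.0)
    return A + A.T
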