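"""Nodal graph-topology metrics for weighted and binary brain networks.

All functions operate on dense symmetric adjacency matrices with a zero
diagonal: binary 0/1 matrices for cost-thresholded functional networks and
non-negative weight matrices in [0, 1] for structural networks.  The five
nodal properties mirror the Brain Connectivity Toolbox conventions:

* strength / degree          -- row sum of weights / edges
* nodal global efficiency    -- mean inverse shortest-path distance to all
                                other nodes
* nodal local efficiency     -- global efficiency of the subgraph induced by
                                a node's neighbours
* clustering coefficient     -- binary triangle fraction, or the Onnela
                                geometric-mean formula for weighted graphs
* betweenness centrality     -- Brandes shortest-path betweenness, normalised
                                by (n-1)(n-2)/2 by default

Weighted shortest paths use the connection-length transform ``l = 1/w``.
Unreachable pairs have infinite distance and contribute zero efficiency.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "shortest_path_lengths",
    "nodal_strength",
    "nodal_degree",
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "nodal_clustering_coefficient",
    "betweenness_centrality",
    "compute_nodal_metrics",
    "average_metrics_over_costs",
    "assemble_feature_vector",
    "feature_names",
    "METRIC_NAMES",
]

#: Canonical metric order used everywhere a feature vector is assembled.
METRIC_NAMES = (
    "strength",
    "global_efficiency",
    "local_efficiency",
    "clustering",
    "betweenness",
)

_DIST_TOL = 1e-10


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if np.any(A < 0):
        raise ValueError("adjacency must be non-negative")
    return A


def _length_matrix(A: np.ndarray, weighted: bool) -> np.ndarray:
    """Connection lengths: 1/w for weighted graphs, 1 per edge for binary."""
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, (1.0 / A) if weighted else 1.0, np.inf)
    np.fill_diagonal(L, np.inf)
    return L


def _floyd_warshall(L: np.ndarray) -> np.ndarray:
    """Dense all-pairs shortest paths from a length matrix (inf = no edge)."""
    D = L.copy()
    np.fill_diagonal(D, 0.0)
    for k in range(D.shape[0]):
        np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :], out=D)
    return D


def shortest_path_lengths(A: np.ndarray, weighted: bool = False) -> np.ndarray:
    """All-pairs shortest-path distance matrix.

    Binary graphs use hop counts; weighted graphs use the ``1/w`` connection
    lengths.  Unreachable pairs are ``inf`` and the diagonal is 0.  The
    networks here are small and dense, so a vectorised Floyd-Warshall beats
    sparse-graph machinery.
    """
    A = _check_adjacency(A)
    return _floyd_warshall(_length_matrix(A, weighted))


def nodal_strength(W: np.ndarray) -> np.ndarray:
    """Sum of a node's edge weights."""
    return _check_adjacency(W).sum(axis=1)


def nodal_degree(A: np.ndarray) -> np.ndarray:
    """Number of edges incident to a node."""
    return (_check_adjacency(A) > 0).sum(axis=1).astype(float)


def _efficiency_from_distances(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_global_efficiency(A: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Average inverse shortest-path distance from each node to all others."""
    return _efficiency_from_distances(shortest_path_lengths(A, weighted=weighted))


def nodal_local_efficiency(A: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Global efficiency of the subgraph induced by each node's neighbours.

    Nodes with fewer than two neighbours score 0.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    L = _length_matrix(A, weighted)
    k = (A > 0).sum(axis=1)
    kmax = int(k.max()) if n else 0
    if kmax < 2:
        return np.zeros(n)
    # gather every node's neighbourhood into one padded (n, kmax, kmax)
    # tensor and run Floyd-Warshall batched over the leading axis; padded
    # slots are held at +inf so they never act as intermediates
    mask = A > 0
    # stable argsort floats neighbours (True) to the front in index order
    idx = np.argsort(~mask, axis=1, kind="stable")[:, :kmax]
    valid = np.arange(kmax)[None, :] < k[:, None]
    S = L[idx[:, :, None], idx[:, None, :]]
    pad = ~(valid[:, :, None] & valid[:, None, :])
    S[pad] = np.inf
    for m in range(kmax):
        np.minimum(S, S[:, :, m:m + 1] + S[:, m:m + 1, :], out=S)
    with np.errstate(divide="ignore"):
        inv = 1.0 / S
    inv[~np.isfinite(inv)] = 0.0
    inv[pad] = 0.0
    inv[:, np.arange(kmax), np.arange(kmax)] = 0.0
    denom = k * (k - 1)
    return np.where(k >= 2, inv.sum(axis=(1, 2)) / np.where(denom > 0, denom, 1),
                    0.0)


def nodal_clustering_coefficient(A: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Triangle density around each node.

    Binary: ``2 t_i / (k_i (k_i - 1))`` with ``t_i`` the triangle count.
    Weighted: Onnela's formula -- the same expression with ``t_i`` replaced by
    the sum of geometric means of max-normalised triangle weights.
    """
    A = _check_adjacency(A)
    mask = (A > 0).astype(float)
    k = mask.sum(axis=1)
    denom = k * (k - 1)
    if weighted:
        wmax = A.max()
        What = np.cbrt(A / wmax) if wmax > 0 else A
        cyc = np.diag(What @ What @ What)
    else:
        cyc = np.diag(mask @ mask @ mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc / denom, 0.0)
    return c


def betweenness_centrality(A: np.ndarray, weighted: bool = False,
                           normalized: bool = True) -> np.ndarray:
    """Fraction of all-pairs shortest paths passing through each node.

    Brandes accumulation driven by a precomputed distance matrix; nodes are
    processed in non-decreasing distance order from each source, batched by
    distance value so binary graphs sweep one BFS level per step.  Normalised
    by ``(n-1)(n-2)/2`` unless ``normalized=False``.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if n < 3:
        return np.zeros(n)
    if not weighted:
        return _betweenness_binary(A, normalized)
    D = shortest_path_lengths(A, weighted=weighted)
    L = _length_matrix(A, weighted=weighted)
    # predecessor tensor P[s, u, v]: edge (u, v) lies on a shortest path
    # from s through u to v
    with np.errstate(invalid="ignore"):
        P = (np.isfinite(L)[None, :, :]
             & (np.abs(D[:, :, None] + L[None, :, :] - D[:, None, :])
                < _DIST_TOL))
    reach = np.isfinite(D)
    P &= reach[:, :, None] & reach[:, None, :]
    Pf = P.astype(float)
    # process nodes in per-source distance order, one rank at a time, so a
    # node's predecessors (strictly closer) are always handled before it
    order = np.argsort(D, axis=1)
    src = np.arange(n)
    sigma = np.eye(n)
    for r in range(1, n):
        v = order[:, r]
        ok = reach[src, v]
        vals = np.einsum("su,su->s", sigma, Pf[src, :, v])
        sigma[src[ok], v[ok]] = vals[ok]
    delta = np.zeros((n, n))
    for r in range(n - 1, 0, -1):
        v = order[:, r]
        sig_v = sigma[src, v]
        ok = reach[src, v] & (sig_v > 0)
        coef = np.where(ok, (1.0 + delta[src, v]) / np.where(ok, sig_v, 1.0),
                        0.0)
        delta += Pf[src, :, v] * coef[:, None] * sigma
    np.fill_diagonal(delta, 0.0)  # sources accumulate no dependency
    bc = delta.sum(axis=0) / 2.0  # each pair counted from both endpoints
    if normalized:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def _betweenness_binary(A: np.ndarray, normalized: bool) -> np.ndarray:
    """Brandes betweenness for binary graphs, batched over all sources.

    Path counting and dependency accumulation sweep BFS levels with one
    einsum per level over the (source, node, node) predecessor tensor.
    """
    n = A.shape[0]
    mask = A > 0
    D = shortest_path_lengths(A, weighted=False)
    # P[s, u, v]: edge (u, v) on a shortest path from s through u to v
    P = mask[None, :, :] & (D[:, :, None] + 1 == D[:, None, :])
    Pf = P.astype(float)
    finite = np.isfinite(D)
    max_lev = int(D[finite].max()) if finite.any() else 0
    sigma = np.eye(n)
    for lev in range(1, max_lev + 1):
        at_lev = D == lev
        if not at_lev.any():
            break
        tmp = np.einsum("su,suv->sv", sigma, Pf)
        sigma[at_lev] = tmp[at_lev]
    delta = np.zeros((n, n))
    for lev in range(max_lev, 0, -1):
        at_lev = D == lev
        coef = np.where(at_lev, (1.0 + delta) / np.where(sigma > 0, sigma, 1.0), 0.0)
        delta += np.einsum("suv,sv->su", Pf, coef) * sigma
    np.fill_diagonal(delta, 0.0)  # the source itself accumulates no dependency
    bc = delta.sum(axis=0) / 2.0
    if normalized:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def compute_nodal_metrics(A: np.ndarray, weighted: bool,
                          normalized_betweenness: bool = True
                          ) -> dict[str, np.ndarray]:
    """All five nodal metrics for one network, keyed by `METRIC_NAMES`."""
    return {
        "strength": nodal_strength(A) if weighted else nodal_degree(A),
        "global_efficiency": nodal_global_efficiency(A, weighted=weighted),
        "local_efficiency": nodal_local_efficiency(A, weighted=weighted),
        "clustering": nodal_clustering_coefficient(A, weighted=weighted),
        "betweenness": betweenness_centrality(A, weighted=weighted,
                                              normalized=normalized_betweenness),
    }


def average_metrics_over_costs(adjacencies: Sequence[np.ndarray],
                               normalized_betweenness: bool = True
                               ) -> dict[str, np.ndarray]:
    """Binary nodal metrics averaged across a set of cost-thresholded graphs.

    This is the area-under-the-cost-curve style aggregation that reduces a
    retained cost range to one value per node per metric.
    """
    if len(adjacencies) == 0:
        raise ValueError("need at least one adjacency matrix")
    acc: dict[str, np.ndarray] | None = None
    for A in adjacencies:
        m = compute_nodal_metrics(A, weighted=False,
                                  normalized_betweenness=normalized_betweenness)
        if acc is None:
            acc = m
        else:
            for key in acc:
                acc[key] = acc[key] + m[key]
    assert acc is not None
    return {key: val / len(adjacencies) for key, val in acc.items()}


def feature_names(n_struct: int = 78, n_func: int = 59) -> list[str]:
    """Deterministic feature ordering: modality -> metric -> node index.

    ``struct_<metric>_<node>`` for the weighted structural network followed by
    ``func_<metric>_<node>`` for the cost-averaged functional networks.
    """
    names = [f"struct_{m}_{i}" for m in METRIC_NAMES for i in range(n_struct)]
    names += [f"func_{m}_{i}" for m in METRIC_NAMES for i in range(n_func)]
    return names


def assemble_feature_vector(structural: Mapping[str, np.ndarray] | None,
                            functional: Mapping[str, np.ndarray] | None
                            ) -> pd.Series:
    """Concatenate nodal metric dictionaries into one named feature vector.

    With the default 78-node structural and 59-node functional networks this
    yields 390 + 295 = 685 features.  Either modality may be omitted.
    """
    if structural is None and functional is None:
        raise ValueError("at least one modality required")
    parts: list[pd.Series] = []
    for prefix, metrics in (("struct", structural), ("func", functional)):
        if metrics is None:
            continue
        sizes = {len(np.asarray(metrics[m])) for m in METRIC_NAMES}
        if len(sizes) != 1:
            raise ValueError(f"{prefix} metric vectors have inconsistent lengths: {sizes}")
        n = sizes.pop()
        vals = np.concatenate([np.asarray(metrics[m], dtype=float) for m in METRIC_NAMES])
        idx = [f"{prefix}_{m}_{i}" for m in METRIC_NAMES for i in range(n)]
        parts.append(pd.Series(vals, index=idx))
    return pd.concat(parts)
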