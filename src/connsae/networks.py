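"""Construction of weighted structural and binarised functional brain networks.

The structural network is built from a symmetric matrix of probabilistic
tractography streamline counts: each non-zero edge weight is the
log-transformed count divided by the maximum log-transformed count in the
same network, giving weights in (0, 1] with the strongest edge at 1.

The functional network is built from an ROI-by-ROI correlation matrix of
task-fMRI time series, binarised over a range of network costs (fractions of
possible edges retained).  A cost is kept when the resulting graph is
small-world, i.e. its sigma index ``(C/C_rand)/(L/L_rand)`` against
degree-preserving rewired references exceeds a threshold; the retained costs
form a contiguous range and downstream nodal metrics are averaged across it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import nodal_clustering_coefficient, shortest_path_lengths

__all__ = [
    "StructuralNetwork",
    "FunctionalNetworkSet",
    "SmallWorldRangeError",
    "build_structural_network",
    "binarize_at_cost",
    "small_world_sigma",
    "select_smallworld_cost_range",
    "DEFAULT_COST_GRID",
    "DEFAULT_SIGMA_THRESHOLD",
]

#: Cost grid spanning sparse-but-connected through clearly dense graphs.
DEFAULT_COST_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.41, 0.02), 2))
DEFAULT_SIGMA_THRESHOLD = 1.1


class SmallWorldRangeError(ValueError):
    """No cost in the grid satisfied the small-world criterion."""


@dataclass
class StructuralNetwork:
    """Weighted structural connectome: symmetric weights in [0, 1], zero diagonal."""

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not self.node_labels:
            self.node_labels = [f"node_{i}" for i in range(W.shape[0])]
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class FunctionalNetworkSet:
    """Binary functional networks over the retained small-world cost range."""

    adjacencies: list[np.ndarray]
    costs: list[float]
    sigma_per_cost: dict[float, float]

    @property
    def n_nodes(self) -> int:
        return self.adjacencies[0].shape[0]


def _symmetrize_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"count matrix must be square, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be non-negative")
    # directed tractography counts are averaged in both directions
    return (counts + counts.T) / 2.0


def build_structural_network(counts: np.ndarray,
                             node_labels: list[str] | None = None
                             ) -> StructuralNetwork:
    """Log-transform and max-normalise streamline counts into edge weights.

    ``w_ij = ln(1 + s_ij) / max_kl ln(1 + s_kl)`` for non-zero counts, 0
    otherwise.  The +1 offset keeps single-streamline edges non-zero and the
    transform well defined; after max-normalisation the base of the logarithm
    is immaterial.
    """
    s = _symmetrize_counts(counts)
    np.fill_diagonal(s, 0.0)
    logs = np.log1p(s)
    mx = logs.max()
    if mx <= 0:
        raise ValueError("count matrix has no non-zero off-diagonal entries")
    W = logs / mx
    np.fill_diagonal(W, 0.0)
    return StructuralNetwork(weights=W, node_labels=node_labels or [])


def _edge_order(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending value, ties by (row, col)."""
    n = corr.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = corr[rows, cols]
    # lexsort: last key is primary
    order = np.lexsort((cols, rows, -vals))
    return rows[order], cols[order]


def binarize_at_cost(corr: np.ndarray, cost: float) -> np.ndarray:
    """Keep the ``round(cost * n(n-1)/2)`` strongest correlations as edges.

    Ranking is by signed correlation value; boundary ties are broken by
    ascending (row, column) index so the output is deterministic.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    if not (0 < cost <= 1):
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    n = corr.shape[0]
    n_edges = int(round(cost * n * (n - 1) / 2))
    rows, cols = _edge_order(corr)
    A = np.zeros((n, n))
    keep_r, keep_c = rows[:n_edges], cols[:n_edges]
    A[keep_r, keep_c] = 1.0
    A[keep_c, keep_r] = 1.0
    return A


def _characteristic_path_length(A: np.ndarray) -> float:
    """Mean shortest-path length over reachable node pairs."""
    D = shortest_path_lengths(A, weighted=False)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(D)
    if not finite.any():
        return np.inf
    return float(D[finite].mean())


def _rewire_degree_preserving(A: np.ndarray, rng: np.random.Generator,
                              n_swap_per_edge: int = 10) -> np.ndarray:
    """Random reference graph via double-edge swaps (degree sequence kept)."""
    A = A.copy()
    rows, cols = np.triu_indices(A.shape[0], k=1)
    edge_mask = A[rows, cols] > 0
    edges = list(zip(rows[edge_mask].tolist(), cols[edge_mask].tolist()))
    m = len(edges)
    if m < 2:
        return A
    attempts = n_swap_per_edge * m
    idx_pairs = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for (i, j), flip in zip(idx_pairs, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,c),(b,d)
        if len({a, b, c, d}) < 4:
            continue
        if A[a, c] or A[b, d]:
            continue
        A[a, b] = A[b, a] = 0.0
        A[c, d] = A[d, c] = 0.0
        A[a, c] = A[c, a] = 1.0
        A[b, d] = A[d, b] = 1.0
        edges[i] = (min(a, c), max(a, c))
        edges[j] = (min(b, d), max(b, d))
    return A


def small_world_sigma(adj: np.ndarray, n_random: int = 20,
                      seed: int | np.random.Generator | None = 0) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    ``C`` is the mean binary clustering coefficient and ``L`` the
    characteristic path length (over reachable pairs only, when the graph is
    disconnected); reference values are averaged over ``n_random``
    degree-preserving rewired graphs.  Values above 1 indicate clustering in
    excess of random with near-random path length.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    A = (np.asarray(adj, dtype=float) > 0).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = float(nodal_clustering_coefficient(A, weighted=False).mean())
    L = _characteristic_path_length(A)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for r in range(n_random):
        R = _rewire_degree_preserving(A, rng)
        c_rand[r] = nodal_clustering_coefficient(R, weighted=False).mean()
        l_rand[r] = _characteristic_path_length(R)
    C_rand = float(c_rand.mean())
    L_rand = float(l_rand.mean())
    if C_rand <= 0 or not np.isfinite(L) or L <= 0:
        return 0.0
    return (C / C_rand) / (L / L_rand)


def select_smallworld_cost_range(corr: np.ndarray,
                                 cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
                                 sigma_threshold: float = DEFAULT_SIGMA_THRESHOLD,
                                 n_random: int = 20,
                                 seed: int | None = 0) -> FunctionalNetworkSet:
    """Binarise over the contiguous cost range that is small-world.

    Sigma is evaluated on the graph binarised at each grid cost; the longest
    contiguous run of costs with sigma strictly above the threshold is
    retained (the first such run on ties).  Raises `SmallWorldRangeError`
    when no cost qualifies.
    """
    grid = list(cost_grid)
    if any(not (0 < c <= 1) for c in grid) or sorted(grid) != grid:
        raise ValueError("cost_grid must be ascending within (0, 1]")
    rng = np.random.default_rng(seed)
    adjs = {c: binarize_at_cost(corr, c) for c in grid}
    sigmas = {c: small_world_sigma(adjs[c], n_random=n_random, seed=rng)
              for c in grid}
    ok = [sigmas[c] > sigma_threshold for c in grid]
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(ok + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if best_len == 0:
        raise SmallWorldRangeError(
            f"no cost in {grid} reached sigma > {sigma_threshold}; "
            f"sigmas were {sigmas}"
        )
    kept = grid[best_start:best_start + best_len]
    return FunctionalNetworkSet(
        adjacencies=[adjs[c] for c in kept],
        costs=kept,
        sigma_per_cost={c: float(sigmas[c]) for c in grid},
    )
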