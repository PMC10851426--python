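"""Topological metrics on binary undirected graphs.

Conventions (all on symmetric boolean adjacency without self-loops):

* ``C`` — mean of nodal clustering coefficients (Watts-Strogatz), with
  nodes of degree < 2 contributing 0. The transitivity ratio is available
  separately but is *not* what small-world gamma normalizes.
* ``Lp`` — mean shortest-path length over ordered pairs with a connecting
  path; disconnected pairs are excluded from the mean (not substituted).
* ``Eglobal`` / ``NE`` — mean inverse shortest-path length with 1/inf = 0,
  over all pairs / per node.
* ``Elocal`` — per node, the global efficiency of the subgraph induced by
  its neighbors (0 for degree < 2); the global value is the nodal mean.
* ``BC`` — Brandes betweenness, unnormalized, undirected (each unordered
  pair counted once, fractional credit for equal-length paths); delegated
  to networkx.
* ``DC`` — degree (row sums).

All distance-based metrics share one all-pairs BFS computed by boolean
matrix products, which is fast for the small dense graphs of a density
sweep. AUC summaries are trapezoidal integrals over the density axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "shortest_path_lengths",
    "clustering_coefficient",
    "transitivity",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "degree",
    "nodal_efficiency",
    "global_metrics",
    "nodal_metrics",
    "auc_over_sweep",
]

GLOBAL_METRIC_NAMES = ("C", "Lp", "Eglobal", "Elocal")
NODAL_METRIC_NAMES = ("BC", "DC", "NE")
SMALL_WORLD_NAMES = ("gamma", "lambda", "sigma")


@dataclass(frozen=True)
class GlobalMetrics:
    """Global topology summary of one binary graph."""

    C: float
    Lp: float
    Eglobal: float
    Elocal: float


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node metrics of one binary graph (arrays of length N)."""

    BC: np.ndarray
    DC: np.ndarray
    NE: np.ndarray


def _as_bool_adj(adj: np.ndarray) -> np.ndarray:
    A = np.asarray(adj)
    A = A.astype(bool) if A.dtype != bool else A
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances; inf for no path.

    BFS by repeated (float32 BLAS) frontier-times-adjacency products —
    O(diameter) matrix multiplications, which beats per-source BFS for the
    small dense graphs this package analyses.
    """
    A = _as_bool_adj(adj)
    n = A.shape[0]
    Af = A.astype(np.float32)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[A] = 1.0
    reach = A | np.eye(n, dtype=bool)
    frontier = A.astype(np.float32)
    d = 1
    while True:
        nxt = (frontier @ Af) > 0
        newly = nxt & ~reach
        if not newly.any():
            return D
        d += 1
        D[newly] = d
        reach |= newly
        frontier = newly.astype(np.float32)


def clustering_coefficient(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Watts-Strogatz clustering: (mean over all nodes, per-node values)."""
    A = _as_bool_adj(adj).astype(np.float32)
    # triangle/degree counts are small integers: exact in float32, but the
    # divisions are done in float64 so values agree with exact enumeration
    k = A.sum(axis=1).astype(np.float64)
    tri = (((A @ A) * A).sum(axis=1) / 2.0).astype(np.float64)
    denom = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean()), c


def transitivity(adj: np.ndarray) -> float:
    """Global transitivity ratio 3*triangles / open triads (extra output)."""
    A = _as_bool_adj(adj).astype(np.float32)
    k = A.sum(axis=1)
    closed = float(((A @ A) * A).sum())  # = 6 * n_triangles
    triads = float((k * (k - 1)).sum())
    return closed / triads if triads > 0 else 0.0


def characteristic_path_length(adj: np.ndarray) -> float:
    """Mean finite shortest-path length over ordered pairs i != j.

    Disconnected pairs are excluded from the mean. A graph with no edges
    has no finite pair and raises ValueError.
    """
    D = shortest_path_lengths(adj)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValueError("characteristic path length undefined: no edges")
    return float(D[finite].mean())


def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d(i,j) over ordered pairs i != j, with 1/inf = 0."""
    D = shortest_path_lengths(adj)
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(D)
    np.divide(1.0, D, out=inv, where=np.isfinite(D) & off)
    return float(inv[off].mean())


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """NE(i) = mean over j != i of 1/d(i,j), with 1/inf = 0."""
    D = shortest_path_lengths(adj)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(D)
    np.divide(1.0, D, out=inv, where=np.isfinite(D) & off)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Per node, global efficiency of the neighbor-induced subgraph.

    Nodes with fewer than 2 neighbors contribute 0. Returns (mean, per-node).
    """
    A = _as_bool_adj(adj)
    n = A.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if nb.size < 2:
            continue
        e[i] = global_efficiency(A[np.ix_(nb, nb)])
    return float(e.mean()), e


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized Brandes betweenness centrality (undirected counting)."""
    A = _as_bool_adj(adj)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])], dtype=float)


def degree(adj: np.ndarray) -> np.ndarray:
    """Degree centrality: row sums of the adjacency."""
    return _as_bool_adj(adj).sum(axis=1).astype(float)


def global_metrics(adj: np.ndarray) -> GlobalMetrics:
    C, _ = clustering_coefficient(adj)
    El, _ = local_efficiency(adj)
    return GlobalMetrics(
        C=C,
        Lp=characteristic_path_length(adj),
        Eglobal=global_efficiency(adj),
        Elocal=El,
    )


def nodal_metrics(adj: np.ndarray) -> NodalMetrics:
    return NodalMetrics(
        BC=betweenness(adj), DC=degree(adj), NE=nodal_efficiency(adj)
    )


def distance_summaries(D: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(Lp, Eglobal, NE) from a precomputed distance matrix.

    Shared fast path for sweep loops: one BFS serves all distance-based
    metrics. Lp is NaN if no finite pair exists.
    """
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    lp = float(D[finite].mean()) if finite.any() else float("nan")
    inv = np.zeros_like(D)
    np.divide(1.0, D, out=inv, where=finite)
    ne = inv.sum(axis=1) / (n - 1)
    return lp, float(inv[off].mean()), ne


def auc_over_sweep(values: np.ndarray, densities: np.ndarray) -> float | np.ndarray:
    """Trapezoidal integral of a metric curve over the density axis.

    ``values`` may be a vector (one value per density) or a matrix with one
    row per density (nodal curves), in which case a per-column AUC vector is
    returned.
    """
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if values.shape[0] != densities.shape[0]:
        raise ValueError(
            f"{values.shape[0]} values vs {densities.shape[0]} densities"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("metric curve contains non-finite values")
    out = np.trapezoid(values, densities, axis=0)
    return float(out) if np.ndim(out) == 0 else out
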