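"""Group-level covariance network construction.

Pipeline stage: per-group covariate residualization of regional thickness,
Pearson correlation across subjects (one network per group), and
density-based binarization over a sweep of target densities. Thresholding
at a fixed density — rather than at a fixed correlation value — guarantees
that the two group networks have identical node and edge counts at every
point of the sweep, which is what makes their topological metrics
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import ThicknessDataset

__all__ = [
    "DensitySweep",
    "CovarianceNetwork",
    "DensityGraphStack",
    "residualize",
    "build_scn",
    "threshold_stack",
    "check_density_validity",
]

logger = logging.getLogger("scnkit")

Scope = Literal["per-group", "pooled"]
EdgeRank = Literal["signed", "absolute"]


@dataclass(frozen=True)
class DensitySweep:
    """Target network densities: ``d_min`` to ``d_max`` in steps of ``step``.

    Defaults cover 0.10-0.40 in steps of 0.01 (31 points): below ~0.1 a
    148-node network risks having fewer edges than nodes (fragmentation),
    while far above 0.4 binary networks approach random configurations.
    """

    d_min: float = 0.10
    d_max: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min <= self.d_max < 1.0):
            raise ValueError(
                f"need 0 < d_min <= d_max < 1, got [{self.d_min}, {self.d_max}]"
            )
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")

    @property
    def densities(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return self.d_min + self.step * np.arange(n)


@dataclass
class CovarianceNetwork:
    """One group's residualized region-by-region Pearson correlation matrix."""

    group: str
    corr: np.ndarray
    covariates_removed: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("corr must be a square matrix")
        if not np.all(np.isfinite(c)):
            raise ValueError("corr contains non-finite values")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if np.abs(c).max() > 1.0 + 1e-12:
            raise ValueError("corr values must lie in [-1, 1]")
        np.fill_diagonal(c, 0.0)
        self.corr = c

    @property
    def n_nodes(self) -> int:
        return self.corr.shape[0]


@dataclass
class DensityGraphStack:
    """Nested binary adjacency matrices across a density sweep.

    ``adj[k]`` is the symmetric boolean adjacency at ``densities[k]``; edge
    sets are nested (monotone in density) because all densities rank edges
    by the same ordering of correlation values.
    """

    densities: np.ndarray
    adj: np.ndarray  # (n_densities, N, N) bool
    group: str = ""

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.adj = np.asarray(self.adj, dtype=bool)
        if self.adj.ndim != 3 or self.adj.shape[0] != len(self.densities):
            raise ValueError("adj must be (n_densities, N, N)")

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[1]

    def edge_counts(self) -> np.ndarray:
        return self.adj.sum(axis=(1, 2)) // 2

    def __iter__(self):
        return iter(self.adj)

    def __len__(self) -> int:
        return len(self.densities)


def _design_matrix(
    cov: pd.DataFrame, covariate_names: Sequence[str]
) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(cov))]
        + [cov[name].to_numpy(dtype=float) for name in covariate_names]
    )
    return X


def _check_rank(X: np.ndarray, covariate_names: Sequence[str], label: str) -> None:
    for j, name in enumerate(covariate_names, start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(
                f"design for group {label!r} is rank-deficient: covariate "
                f"{name!r} is constant"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design for group {label!r} is rank-deficient: covariates "
            f"{list(covariate_names)} are collinear"
        )


def residualize(
    ds: ThicknessDataset,
    covariate_names: Sequence[str] = ("age", "sex", "tiv"),
    scope: Scope = "per-group",
) -> dict[str, np.ndarray]:
    """Remove covariate effects from thickness by per-region least squares.

    For each region, thickness is regressed on an intercept plus the named
    covariates; residuals are returned per group as (n_subjects_in_group x
    n_regions) arrays. With ``scope="per-group"`` (default, the standard
    practice for group-specific covariance networks) the regressions are fit
    within each group separately; ``"pooled"`` fits one regression on all
    subjects and then splits the residuals by group.
    """
    missing = [c for c in covariate_names if c not in ds.covariates.columns]
    if missing:
        raise ValueError(f"covariate(s) not in dataset: {missing}")
    Y_all = ds.thickness.to_numpy(dtype=float)
    out: dict[str, np.ndarray] = {}
    if scope == "pooled":
        X = _design_matrix(ds.covariates, covariate_names)
        _check_rank(X, covariate_names, "pooled")
        beta, *_ = np.linalg.lstsq(X, Y_all, rcond=None)
        resid = Y_all - X @ beta
        for label in ds.group_order:
            out[label] = resid[ds.group_mask(label)]
    elif scope == "per-group":
        for label in ds.group_order:
            mask = ds.group_mask(label)
            X = _design_matrix(ds.covariates[mask], covariate_names)
            _check_rank(X, covariate_names, label)
            beta, *_ = np.linalg.lstsq(X, Y_all[mask], rcond=None)
            out[label] = Y_all[mask] - X @ beta
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out


def residualize_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``Y`` on design ``X`` (no rank checks).

    Internal fast path used inside permutation loops where the design has
    already been validated once on the observed labels.
    """
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def correlation_matrix(residuals: np.ndarray) -> np.ndarray:
    """Pearson correlation between regions across subjects, diagonal zeroed.

    Zero-variance regions get correlation 0 with every partner (logged)
    rather than NaN, keeping the matrix finite.
    """
    sd = residuals.std(axis=0)
    scale = np.abs(residuals).max() if residuals.size else 1.0
    dead = sd <= 1e-12 * max(scale, 1.0)  # constant up to float rounding
    if dead.any():
        logger.warning(
            "%d zero-variance region(s); their correlations set to 0",
            int(dead.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(residuals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    if dead.any():
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    return corr


def build_scn(
    residuals: np.ndarray,
    group: str,
    covariates_removed: Sequence[str] = ("age", "sex", "tiv"),
) -> CovarianceNetwork:
    """Build one group's structural covariance network from residuals."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[0] < 4:
        raise ValueError(
            f"group {group!r} has {residuals.shape[0]} subjects; >= 4 required"
        )
    return CovarianceNetwork(group, correlation_matrix(residuals), tuple(covariates_removed))


def rank_edges(corr: np.ndarray, edge_rank: EdgeRank = "signed") -> np.ndarray:
    """Upper-triangle pair indices ordered strongest-first.

    ``signed`` ranks by the raw correlation (most positive first);
    ``absolute`` by |r|. Ties at any cutoff resolve deterministically by
    lexicographic (i, j) node order, because the pair list is generated in
    lexicographic order and the sort is stable.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    if edge_rank == "absolute":
        vals = np.abs(vals)
    elif edge_rank != "signed":
        raise ValueError(f"unknown edge_rank {edge_rank!r}")
    order = np.argsort(-vals, kind="stable")
    return np.column_stack([iu[order], ju[order]])


def edge_count_at(density: float, n_nodes: int) -> int:
    """Exact edge count at a target density: round(d * N(N-1)/2)."""
    return int(round(density * n_nodes * (n_nodes - 1) / 2.0))


def threshold_stack(
    net: CovarianceNetwork,
    sweep: DensitySweep = DensitySweep(),
    edge_rank: EdgeRank = "signed",
) -> DensityGraphStack:
    """Binarize a correlation matrix at every density of the sweep.

    At density ``d`` the ``K = round(d * N(N-1)/2)`` strongest edges are
    kept. Because every density uses the same edge ranking, the stacks are
    nested and edge counts are exact by construction.
    """
    n = net.n_nodes
    ranked = rank_edges(net.corr, edge_rank)
    densities = sweep.densities
    counts = [edge_count_at(d, n) for d in densities]
    if min(counts) < 1:
        raise ValueError(
            f"density {densities[int(np.argmin(counts))]:.3f} on {n} nodes "
            "yields < 1 edge"
        )
    adj = np.zeros((len(densities), n, n), dtype=bool)
    running = np.zeros((n, n), dtype=bool)
    prev = 0
    for k, K in enumerate(counts):
        new = ranked[prev:K]
        running[new[:, 0], new[:, 1]] = True
        running[new[:, 1], new[:, 0]] = True
        prev = K
        adj[k] = running
    return DensityGraphStack(densities, adj, group=net.group)


def check_density_validity(stack: DensityGraphStack) -> pd.DataFrame:
    """Per-density edge count, connected components, and fragmentation flag.

    A network is flagged fragmented when it has fewer edges than nodes (it
    then cannot be connected).
    """
    rows = []
    n = stack.n_nodes
    for d, A in zip(stack.densities, stack.adj):
        n_edges = int(A.sum()) // 2
        n_comp, _ = connected_components(csr_matrix(A), directed=False)
        rows.append(
            {
                "density": float(d),
                "n_edges": n_edges,
                "n_components": int(n_comp),
                "fragmented": n_edges < n,
            }
        )
    return pd.DataFrame(rows)
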