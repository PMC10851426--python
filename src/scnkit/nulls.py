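"""Degree-preserving random-graph null models and small-world indices.

Observed clustering and path length are only interpretable against a null
family of random graphs with matched degrees. The rewiring null uses
Maslov-Sneppen double-edge swaps: pick two edges (a,b), (c,d) and replace
them with (a,d), (c,b), rejecting any swap that would create a self-loop
or a duplicate edge. The degree sequence is conserved exactly by
construction. An Erdos-Renyi null (matching only size and edge count) is
provided as an alternative.

Small-world indices: gamma = C_real / mean(C_rand),
lambda = Lp_real / mean(Lp_rand), sigma = gamma / lambda; sigma > 1 is the
usual operational definition of small-world organization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import (
    GlobalMetrics,
    characteristic_path_length,
    clustering_coefficient,
)

__all__ = [
    "RandomEnsembleSpec",
    "SmallWorldMetrics",
    "rewire_preserving_degree",
    "random_ensemble",
    "erdos_renyi_null",
    "normalize_small_world",
    "small_world_metrics",
]

logger = logging.getLogger("scnkit")


@dataclass(frozen=True)
class RandomEnsembleSpec:
    """Ensemble parameters: 1000 nulls with 10 attempted swaps per edge by
    default (standard mixing practice for Maslov-Sneppen randomization)."""

    n_random: int = 1000
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError(f"n_random must be >= 1, got {self.n_random}")
        if self.swaps_per_edge < 1:
            raise ValueError(
                f"swaps_per_edge must be >= 1, got {self.swaps_per_edge}"
            )


@dataclass(frozen=True)
class SmallWorldMetrics:
    gamma: float
    lambda_: float
    sigma: float


def rewire_preserving_degree(
    adj: np.ndarray,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Performs ``swaps_per_edge * |E|`` swap *attempts*; attempts that would
    create a self-loop or duplicate edge are rejected (and still count).
    If no attempt at all succeeds — rigid graphs such as a triangle admit
    no valid swap — the input is returned unchanged with a logged note.
    Deterministic given ``seed`` (or an explicit Generator).
    """
    A = np.asarray(adj).astype(bool)
    A = A.copy()
    np.fill_diagonal(A, False)
    iu, ju = np.nonzero(np.triu(A, k=1))
    m = iu.size
    if m < 2:
        raise ValueError(f"need >= 2 edges to rewire, got {m}")
    if rng is None:
        rng = np.random.default_rng(seed)

    edges = np.column_stack([iu, ju])
    edge_set = {(int(i), int(j)) for i, j in edges}
    n_attempts = swaps_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    successes = 0
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # proposed replacement: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    if successes == 0:
        logger.info(
            "no valid double-edge swap found in %d attempts; graph returned "
            "unchanged (rigid degree sequence)",
            n_attempts,
        )
        return np.asarray(adj).astype(bool).copy()
    out = np.zeros_like(A)
    arr = np.array(sorted(edge_set))
    out[arr[:, 0], arr[:, 1]] = True
    out |= out.T
    return out


def random_ensemble(
    adj: np.ndarray, spec: RandomEnsembleSpec = RandomEnsembleSpec()
) -> list[np.ndarray]:
    """Draw ``spec.n_random`` degree-preserving rewirings of ``adj``."""
    rng = np.random.default_rng(spec.seed)
    return [
        rewire_preserving_degree(adj, spec.swaps_per_edge, rng=rng)
        for _ in range(spec.n_random)
    ]


def erdos_renyi_null(
    adj: np.ndarray, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Null matching only node count and edge count (density-only null)."""
    A = np.asarray(adj).astype(bool)
    n = A.shape[0]
    m = int(np.triu(A, k=1).sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(iu.size, size=m, replace=False)
    out = np.zeros_like(A)
    out[iu[chosen], ju[chosen]] = True
    out |= out.T
    return out


def normalize_small_world(
    real: GlobalMetrics, ensemble: Sequence[np.ndarray]
) -> SmallWorldMetrics:
    """gamma/lambda/sigma of a graph against an ensemble of null graphs.

    ``C_rand`` and ``Lp_rand`` are ensemble means of the same metrics.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    c_rand = float(np.mean([clustering_coefficient(A)[0] for A in ensemble]))
    lp_rand = float(np.mean([characteristic_path_length(A) for A in ensemble]))
    if c_rand == 0 or lp_rand == 0:
        raise ValueError("degenerate null ensemble (zero mean C or Lp)")
    gamma = real.C / c_rand
    lam = real.Lp / lp_rand
    return SmallWorldMetrics(gamma=gamma, lambda_=lam, sigma=gamma / lam)


def small_world_metrics(
    adj: np.ndarray, spec: RandomEnsembleSpec = RandomEnsembleSpec()
) -> SmallWorldMetrics:
    """Convenience: compute C/Lp on ``adj``, rewire, and normalize."""
    from .metrics import global_metrics

    return normalize_small_world(global_metrics(adj), random_ensemble(adj, spec))
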