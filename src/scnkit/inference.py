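"""Group inference: AUC permutation tests, FDR, correlations, descriptives.

Because each group contributes a single covariance network, group
differences in network topology cannot be tested subject-by-subject.
Instead, the full pipeline (residualize -> correlate -> threshold ->
metric -> AUC over the density sweep) is treated as a statistic of the
group labeling, and its null distribution is built by permuting group
labels (preserving group sizes) and re-running the pipeline from scratch —
including, by default, re-fitting the covariate regressions within each
permuted group, which keeps the null exchangeable.

The test statistic is the difference in metric AUC (first group minus
second, i.e. patients minus controls); the two-tailed p-value uses the
add-one correction p = (#{|null| >= |observed|} + 1) / (n_perm + 1), so p
is never exactly zero. Nodal metrics are corrected across regions by
Benjamini-Hochberg FDR within each metric family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ThicknessDataset
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    auc_over_sweep,
    betweenness,
    clustering_coefficient,
    distance_summaries,
    local_efficiency,
    shortest_path_lengths,
)
from .network import (
    DensitySweep,
    EdgeRank,
    _design_matrix,
    _check_rank,
    correlation_matrix,
    edge_count_at,
    rank_edges,
    residualize_matrix,
)

__all__ = [
    "PermutationResult",
    "PartialCorrelationResult",
    "permutation_test",
    "run_group_comparison",
    "fdr_bh",
    "partial_correlation",
    "cohort_stats",
    "t_from_summary",
    "two_sample_power",
]

logger = logging.getLogger("scnkit")

_VALID_METRICS = set(GLOBAL_METRIC_NAMES) | set(NODAL_METRIC_NAMES)


@dataclass
class PermutationResult:
    """Outcome of one AUC permutation test.

    ``scope`` is ``"global"`` or ``"node:<region_id>"``; ``observed_diff``
    is AUC(group1) - AUC(group2); ``p_fdr`` is filled for nodal scopes only.
    """

    metric: str
    scope: str
    observed_diff: float
    auc_group1: float
    auc_group2: float
    p: float
    p_fdr: float | None = None
    null_diffs: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class PartialCorrelationResult:
    x: str
    y: str
    r: float
    p: float
    p_bonf: float
    n: int
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# fast pipeline core


def _metric_aucs(
    Y: np.ndarray,
    cov: pd.DataFrame,
    masks: Sequence[np.ndarray],
    covariate_names: Sequence[str],
    densities: np.ndarray,
    counts: Sequence[int],
    global_names: Sequence[str],
    nodal_names: Sequence[str],
    edge_rank: EdgeRank,
    refit_residuals: bool,
    precomputed_resid: np.ndarray | None,
) -> dict[str, list]:
    """AUCs of requested metrics for one labeling (list entry per group)."""
    need_D = bool(
        {"Lp", "Eglobal"} & set(global_names) or "NE" in nodal_names
    )
    out: dict[str, list] = {m: [] for m in (*global_names, *nodal_names)}
    for mask in masks:
        if refit_residuals:
            X = _design_matrix(cov[mask], covariate_names)
            resid = residualize_matrix(Y[mask], X)
        else:
            resid = precomputed_resid[mask]  # type: ignore[index]
        corr = correlation_matrix(resid)
        ranked = rank_edges(corr, edge_rank)
        n = corr.shape[0]
        A = np.zeros((n, n), dtype=bool)
        prev = 0
        curves: dict[str, list] = {m: [] for m in out}
        for K in counts:
            new = ranked[prev:K]
            A[new[:, 0], new[:, 1]] = True
            A[new[:, 1], new[:, 0]] = True
            prev = K
            if "C" in curves:
                curves["C"].append(clustering_coefficient(A)[0])
            if "Elocal" in curves:
                curves["Elocal"].append(local_efficiency(A)[0])
            if need_D:
                lp, eg, ne = distance_summaries(shortest_path_lengths(A))
                if "Lp" in curves:
                    curves["Lp"].append(lp)
                if "Eglobal" in curves:
                    curves["Eglobal"].append(eg)
                if "NE" in curves:
                    curves["NE"].append(ne)
            if "DC" in curves:
                curves["DC"].append(A.sum(axis=1).astype(float))
            if "BC" in curves:
                curves["BC"].append(betweenness(A))
        for m, vals in curves.items():
            out[m].append(auc_over_sweep(np.asarray(vals), densities))
    return out


def _normalize_metric_arg(metrics: str | Sequence[str]) -> tuple[str, ...]:
    names = (metrics,) if isinstance(metrics, str) else tuple(metrics)
    bad = [m for m in names if m not in _VALID_METRICS]
    if bad:
        raise ValueError(
            f"unknown metric(s) {bad}; permutation testing supports "
            f"{sorted(_VALID_METRICS)}"
        )
    return names


def run_group_comparison(
    ds: ThicknessDataset,
    metrics: str | Sequence[str] = ("C", "Lp", "Eglobal", "Elocal"),
    sweep: DensitySweep = DensitySweep(),
    n_perm: int = 1000,
    seed: int = 0,
    covariates: Sequence[str] = ("age", "sex", "tiv"),
    edge_rank: EdgeRank = "signed",
    refit_residuals: bool = True,
    keep_null: bool = False,
    fdr_q: float = 0.05,
) -> list[PermutationResult]:
    """Permutation-test AUC group differences for several metrics at once.

    Global metrics (C, Lp, Eglobal, Elocal) yield one result each; nodal
    metrics (BC, DC, NE) yield one result per region with BH-FDR adjusted
    p-values within the metric family. All requested metrics share the
    same permutations and the same pipeline passes.

    ``refit_residuals=False`` residualizes once on the observed labels and
    only re-splits residuals under permutation (faster, slightly less
    exchangeable null).
    """
    names = _normalize_metric_arg(metrics)
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    global_names = [m for m in names if m in GLOBAL_METRIC_NAMES]
    nodal_names = [m for m in names if m in NODAL_METRIC_NAMES]

    Y = ds.thickness.to_numpy(dtype=float)
    cov = ds.covariates
    g1, g2 = ds.group_order
    mask1, mask2 = ds.group_mask(g1), ds.group_mask(g2)
    # validate the observed designs once; permuted designs reuse the solver
    for label, mask in ((g1, mask1), (g2, mask2)):
        _check_rank(_design_matrix(cov[mask], covariates), covariates, label)
    precomputed = None
    if not refit_residuals:
        X_all = _design_matrix(cov, covariates)
        precomputed = np.empty_like(Y)
        for mask in (mask1, mask2):
            precomputed[mask] = residualize_matrix(Y[mask], X_all[mask])

    densities = sweep.densities
    counts = [edge_count_at(d, ds.n_regions) for d in densities]
    if min(counts) < 1:
        raise ValueError("density sweep yields < 1 edge at its lower end")

    observed = _metric_aucs(
        Y, cov, (mask1, mask2), covariates, densities, counts,
        global_names, nodal_names, edge_rank, refit_residuals, precomputed,
    )

    rng = np.random.default_rng(seed)
    n = ds.n_subjects
    n1 = int(mask1.sum())
    null: dict[str, list] = {m: [] for m in (*global_names, *nodal_names)}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm1 = np.zeros(n, dtype=bool)
        pm1[perm[:n1]] = True
        aucs = _metric_aucs(
            Y, cov, (pm1, ~pm1), covariates, densities, counts,
            global_names, nodal_names, edge_rank, refit_residuals, precomputed,
        )
        for m in null:
            null[m].append(aucs[m][0] - aucs[m][1])

    results: list[PermutationResult] = []
    for m in global_names:
        obs = float(observed[m][0] - observed[m][1])
        nd = np.asarray(null[m], dtype=float)
        p = (np.sum(np.abs(nd) >= abs(obs)) + 1.0) / (n_perm + 1.0)
        results.append(
            PermutationResult(
                metric=m, scope="global", observed_diff=obs,
                auc_group1=float(observed[m][0]),
                auc_group2=float(observed[m][1]),
                p=float(p), null_diffs=nd if keep_null else None,
            )
        )
    for m in nodal_names:
        obs = np.asarray(observed[m][0]) - np.asarray(observed[m][1])
        nd = np.asarray(null[m], dtype=float)  # (n_perm, N)
        pvals = (np.sum(np.abs(nd) >= np.abs(obs)[None, :], axis=0) + 1.0) / (
            n_perm + 1.0
        )
        _, p_adj = fdr_bh(pvals, q=fdr_q)
        for i, region in enumerate(ds.atlas.region_id):
            results.append(
                PermutationResult(
                    metric=m, scope=f"node:{region}",
                    observed_diff=float(obs[i]),
                    auc_group1=float(observed[m][0][i]),
                    auc_group2=float(observed[m][1][i]),
                    p=float(pvals[i]), p_fdr=float(p_adj[i]),
                    null_diffs=nd[:, i] if keep_null else None,
                )
            )
    return results


def permutation_test(
    ds: ThicknessDataset,
    metric: str,
    scope: str = "global",
    sweep: DensitySweep = DensitySweep(),
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> PermutationResult | list[PermutationResult]:
    """Single-metric AUC permutation test.

    Returns one :class:`PermutationResult` for ``scope="global"``, or the
    per-region list for ``scope="nodal"``.
    """
    if scope not in ("global", "nodal"):
        raise ValueError(f"scope must be 'global' or 'nodal', got {scope!r}")
    expected = GLOBAL_METRIC_NAMES if scope == "global" else NODAL_METRIC_NAMES
    if metric not in expected:
        raise ValueError(f"metric {metric!r} is not a {scope} metric {expected}")
    out = run_group_comparison(
        ds, metrics=metric, sweep=sweep, n_perm=n_perm, seed=seed, **kwargs
    )
    return out[0] if scope == "global" else out


def results_table(results: Sequence[PermutationResult]) -> pd.DataFrame:
    """Flatten permutation results into the canonical results-table layout."""
    rows = []
    for r in results:
        region = "GLOBAL" if r.scope == "global" else r.scope.split(":", 1)[1]
        rows.append(
            {
                "region_id": region,
                "metric": r.metric,
                "value_group1": r.auc_group1,
                "value_group2": r.auc_group2,
                "difference": r.observed_diff,
                "p": r.p,
                "p_fdr": r.p_fdr,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing, correlations, descriptives


def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: Sequence[str] | None = None,
    m_tests: int = 1,
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on an intercept plus the covariate
    columns; r is the Pearson correlation of the residuals and p comes from
    t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of freedom.
    ``m_tests`` sets the Bonferroni factor for ``p_bonf``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y and covariates must have equal length")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations, got n={n}, k={k}")
    X = np.column_stack([np.ones(n), Z])
    rx = residualize_matrix(x[:, None], X).ravel()
    ry = residualize_matrix(y[:, None], X).ravel()
    if np.allclose(rx, 0) or rx.std() == 0 or np.allclose(ry, 0) or ry.std() == 0:
        raise ValueError("constant variable after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    if covariate_names is None:
        covariate_names = tuple(f"z{i}" for i in range(k))
    return PartialCorrelationResult(
        x=x_name, y=y_name, r=r, p=p, p_bonf=min(1.0, p * m_tests),
        n=n, covariates=tuple(covariate_names),
    )


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics: (t, df, p)."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def cohort_stats(
    ds: ThicknessDataset,
    variables: Sequence[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Descriptive group comparison of covariates and clinical variables.

    Continuous variables use the pooled-variance two-sample t-test when a
    Shapiro-Wilk check (at ``normality_alpha``, per group) does not reject
    normality in either group, and the Mann-Whitney U-test otherwise. The
    ``sex`` variable uses a Pearson chi-square on the 2x2 table without
    continuity correction. All p-values are two-sided.
    """
    g1, g2 = ds.group_order
    m1, m2 = ds.group_mask(g1), ds.group_mask(g2)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs >= 2 subjects for descriptives")
    if variables is None:
        variables = list(ds.covariates.columns)
    rows = []
    for var in variables:
        v = ds.covariates[var].to_numpy(dtype=float)
        a, b = v[m1], v[m2]
        row = {
            "variable": var,
            f"mean_{g1}": a.mean(), f"sd_{g1}": a.std(ddof=1),
            f"mean_{g2}": b.mean(), f"sd_{g2}": b.std(ddof=1),
        }
        if var == "sex":
            table = np.array(
                [[(a == 1).sum(), (a == 0).sum()],
                 [(b == 1).sum(), (b == 0).sum()]]
            )
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            row.update(test="chi2", statistic=float(chi2), p=float(p))
        else:
            normal = all(
                stats.shapiro(g).pvalue > normality_alpha for g in (a, b)
            )
            if normal:
                t, p = stats.ttest_ind(a, b, equal_var=True)
                row.update(test="t", statistic=float(t), p=float(p))
            else:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                row.update(test="mannwhitney", statistic=float(u), p=float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_power(
    d: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Power of a two-sided two-sample t-test at effect size Cohen's d.

    Uses the noncentral t distribution with df = n1 + n2 - 2 and
    noncentrality d / sqrt(1/n1 + 1/n2).
    """
    if d < 0:
        raise ValueError(f"effect size d must be >= 0, got {d}")
    if n1 <= 1 or n2 <= 1:
        raise ValueError("both sample sizes must exceed 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    df = n1 + n2 - 2
    ncp = d / np.sqrt(1.0 / n1 + 1.0 / n2)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )
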