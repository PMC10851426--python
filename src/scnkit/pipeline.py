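"""End-to-end pipeline orchestration with config echo and logging.

``run_pipeline`` ties the stages together: load (or simulate) a cohort,
describe it, build per-group covariance networks and density stacks,
compute global metric curves (with small-world normalization against
degree-preserving nulls), permutation-test AUC group differences (global
and nodal with FDR), optionally correlate patient-group metrics with
clinical variables, and write everything as TSV tables plus a YAML config
echo and a plain-text log into one output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import load_destrieux_atlas
from .cohort import CohortSpec, generate_cohort
from .inference import (
    cohort_stats,
    partial_correlation,
    results_table,
    run_group_comparison,
)
from .io import ThicknessDataset, read_thickness_table, write_results_table, write_thickness_table
from .metrics import (
    auc_over_sweep,
    clustering_coefficient,
    distance_summaries,
    local_efficiency,
    shortest_path_lengths,
)
from .network import (
    DensitySweep,
    build_scn,
    check_density_validity,
    residualize,
    threshold_stack,
)
from .nulls import RandomEnsembleSpec, normalize_small_world, random_ensemble
from .metrics import GlobalMetrics

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "global_metric_curves"]

logger = logging.getLogger("scnkit")


@dataclass
class RunConfig:
    """Fully serializable run configuration (echoed verbatim to outdir)."""

    output_dir: str = "scn_run"
    thickness_path: str | None = None  # None -> simulate
    covariates_path: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    covariates: tuple[str, ...] = ("age", "sex", "tiv")
    residual_scope: str = "per-group"
    edge_rank: str = "signed"
    density: DensitySweep = field(default_factory=DensitySweep)
    global_metrics: tuple[str, ...] = ("C", "Lp", "Eglobal", "Elocal")
    nodal_metrics: tuple[str, ...] = ("BC", "DC", "NE")
    n_perm: int = 1000
    n_random: int = 1000
    swaps_per_edge: int = 10
    fdr_q: float = 0.05
    correlate: tuple[str, ...] = ()  # "metric:variable" pairs, patient group
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        if isinstance(self.density, dict):
            self.density = DensitySweep(**self.density)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _subseed(seed: int, stage: str) -> int:
    """Independent per-stage stream derived from the master seed.

    Uses crc32 of the stage name (stable across processes, unlike hash()).
    """
    import zlib

    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def global_metric_curves(
    stack, n_random: int = 0, swaps_per_edge: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Per-density global metrics of one stack, optionally with gamma/
    lambda/sigma against ``n_random`` degree-preserving nulls per density."""
    rows = []
    rng = np.random.default_rng(seed)
    for d, A in zip(stack.densities, stack.adj):
        C, _ = clustering_coefficient(A)
        El, _ = local_efficiency(A)
        lp, eg, _ = distance_summaries(shortest_path_lengths(A))
        row = {"density": float(d), "C": C, "Lp": lp, "Eglobal": eg, "Elocal": El}
        if n_random > 0:
            spec = RandomEnsembleSpec(
                n_random=n_random, swaps_per_edge=swaps_per_edge,
                seed=int(rng.integers(2**31)),
            )
            sw = normalize_small_world(
                GlobalMetrics(C=C, Lp=lp, Eglobal=eg, Elocal=El),
                random_ensemble(A, spec),
            )
            row.update(gamma=sw.gamma, **{"lambda": sw.lambda_}, sigma=sw.sigma)
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_curves(curves: dict[str, pd.DataFrame], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [c for c in next(iter(curves.values())).columns if c != "density"]
    for m in metrics:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for group, table in curves.items():
            ax.plot(table["density"], table[m], marker="o", ms=2.5, label=group)
        ax.set_xlabel("network density")
        ax.set_ylabel(m)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"curve_{m}.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Raises with the failing stage named in the log on any error.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "configure"
    try:
        (outdir / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")
        logger.info("scnkit %s; master seed %d", __version__, config.seed)

        stage = "load"
        if config.thickness_path is None:
            spec = dataclasses.replace(
                config.cohort, seed=_subseed(config.seed, "cohort")
            )
            ds = generate_cohort(spec)
            logger.info("simulated cohort: %d subjects x %d regions",
                        ds.n_subjects, ds.n_regions)
            write_thickness_table(ds, outdir / "simulated_cohort.tsv")
        else:
            atlas = load_destrieux_atlas()
            ds = read_thickness_table(
                config.thickness_path, atlas, config.covariates_path
            )
            logger.info("loaded cohort: %d subjects x %d regions",
                        ds.n_subjects, ds.n_regions)

        stage = "descriptives"
        cohort_stats(ds).to_csv(outdir / "cohort_stats.tsv", sep="\t", index=False)

        stage = "networks"
        resid = residualize(ds, config.covariates, scope=config.residual_scope)
        curves: dict[str, pd.DataFrame] = {}
        validity = []
        for label in ds.group_order:
            net = build_scn(resid[label], label, config.covariates)
            stack = threshold_stack(net, config.density, config.edge_rank)
            rep = check_density_validity(stack)
            rep.insert(0, "group", label)
            validity.append(rep)
            curves[label] = global_metric_curves(
                stack, n_random=config.n_random,
                swaps_per_edge=config.swaps_per_edge,
                seed=_subseed(config.seed, f"nulls-{label}"),
            )
            curves[label].to_csv(
                outdir / f"global_curves_{label}.tsv", sep="\t", index=False
            )
        pd.concat(validity).to_csv(
            outdir / "density_validity.tsv", sep="\t", index=False
        )
        if config.plots:
            _plot_curves(curves, outdir)

        stage = "auc-summary"
        auc_rows = []
        for label, table in curves.items():
            for m in table.columns:
                if m == "density":
                    continue
                auc_rows.append(
                    {"group": label, "metric": m,
                     "auc": auc_over_sweep(
                         table[m].to_numpy(), table["density"].to_numpy()
                     )}
                )
        pd.DataFrame(auc_rows).to_csv(
            outdir / "global_auc.tsv", sep="\t", index=False
        )

        stage = "permutation"
        results = run_group_comparison(
            ds,
            metrics=(*config.global_metrics, *config.nodal_metrics),
            sweep=config.density,
            n_perm=config.n_perm,
            seed=_subseed(config.seed, "permutation"),
            covariates=config.covariates,
            edge_rank=config.edge_rank,
            fdr_q=config.fdr_q,
        )
        table = results_table(results)
        write_results_table(
            table[table.region_id == "GLOBAL"], outdir / "global_results.tsv"
        )
        write_results_table(
            table[table.region_id != "GLOBAL"], outdir / "nodal_results.tsv"
        )

        stage = "correlate"
        if config.correlate:
            corr_rows = _clinical_correlations(ds, table, config)
            pd.DataFrame(corr_rows).to_csv(
                outdir / "clinical_correlations.tsv", sep="\t", index=False
            )
        logger.info("pipeline complete: %s", outdir)
        return outdir
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _clinical_correlations(
    ds: ThicknessDataset, table: pd.DataFrame, config: RunConfig
) -> list[dict]:
    """Patient-group partial correlations of nodal AUCs with clinical scores.

    Nodal metric AUCs are subject-free (group-level); following common
    practice the correlation pairs mean regional thickness (patients) with
    the named clinical variable, controlling age, sex, BMI (if present) and
    TIV — pairs are given as "thickness:<variable>".
    """
    rows = []
    mask = ds.group_mask(ds.group_order[0])
    ctrl_names = [
        c for c in ("age", "sex", "bmi", "tiv") if c in ds.covariates.columns
    ]
    Z = ds.covariates.loc[mask, ctrl_names]
    m_tests = len(config.correlate)
    for pair in config.correlate:
        xname, yname = pair.split(":", 1)
        if xname != "thickness":
            raise ValueError(
                f"unsupported correlation source {xname!r}; use 'thickness:<var>'"
            )
        x = ds.thickness.loc[mask].mean(axis=1).to_numpy()
        y = ds.covariates.loc[mask, yname].to_numpy(dtype=float)
        res = partial_correlation(
            x, y, Z, x_name="mean_thickness", y_name=yname,
            covariate_names=ctrl_names, m_tests=m_tests,
        )
        rows.append(dataclasses.asdict(res))
    return rows


def make_fixtures(
    spec: CohortSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write a null cohort (equal loadings) and an effect cohort to disk.

    The null cohort sets both group loadings to the control value; the
    effect cohort keeps the spec's patient/control loadings. Used by the
    test suite and the examples.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    null_spec = dataclasses.replace(spec, loading_patient=spec.loading_control)
    paths = {}
    for name, s in (("null", null_spec), ("effect", spec)):
        ds = generate_cohort(s)
        path = outdir / f"cohort_{name}.tsv"
        write_thickness_table(ds, path)
        paths[name] = path
    return paths
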