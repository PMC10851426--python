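"""Tabular input/output: thickness tables, covariates, and result tables.

File dialect is comma- or tab-separated, auto-detected by extension
(``.csv`` / ``.tsv``), UTF-8, first column = subject id. Thickness and
covariates may live in one merged file (region columns are recognised by
atlas membership) or in a thickness file plus a companion covariate file
sharing subject ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

__all__ = [
    "ThicknessDataset",
    "read_thickness_table",
    "write_thickness_table",
    "write_results_table",
    "RESULT_COLUMNS",
]

logger = logging.getLogger("scnkit")

#: Covariates every subject must have for network construction.
REQUIRED_COVARIATES = ("age", "sex", "tiv")

#: Canonical column order of result tables (extra columns follow these).
RESULT_COLUMNS = (
    "region_id",
    "metric",
    "value_group1",
    "value_group2",
    "difference",
    "p",
    "p_fdr",
)

_SEX_MAP = {"male": 1, "female": 0, "1": 1, "0": 0, 1: 1, 0: 0}


@dataclass
class ThicknessDataset:
    """Subjects x regions cortical thickness with per-subject covariates.

    Attributes
    ----------
    thickness :
        DataFrame, one row per subject, one column per atlas region (mm),
        columns in atlas order.
    covariates :
        DataFrame aligned on the same subject index; must contain ``age``
        (years), ``sex`` (1 = male, 0 = female), ``tiv`` (mm^3); may carry
        clinical/cognitive scores (e.g. HbA1c, CDT, CTT-1).
    group :
        Series of group labels aligned on the subject index, exactly two
        levels with at least 4 subjects each.
    atlas :
        The region atlas fixing node order.
    """

    thickness: pd.DataFrame
    covariates: pd.DataFrame
    group: pd.Series
    atlas: RegionAtlas
    group_order: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.thickness.columns) != list(self.atlas.region_id):
            missing = set(self.atlas.region_id) - set(self.thickness.columns)
            if missing:
                raise ValueError(
                    f"thickness table is missing region column(s): "
                    f"{sorted(missing)[:5]}"
                )
            # same set, wrong order -> realign silently
            self.thickness = self.thickness[list(self.atlas.region_id)]
        values = self.thickness.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite thickness at subject "
                f"{self.thickness.index[bad[0]]!r}, region "
                f"{self.thickness.columns[bad[1]]!r}"
            )
        if np.any(values <= 0):
            bad = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive thickness at subject "
                f"{self.thickness.index[bad[0]]!r}, region "
                f"{self.thickness.columns[bad[1]]!r}"
            )
        if not (
            self.covariates.index.equals(self.thickness.index)
            and self.group.index.equals(self.thickness.index)
        ):
            raise ValueError("thickness, covariates and group must share a subject index")
        for name in REQUIRED_COVARIATES:
            if name not in self.covariates.columns:
                raise ValueError(f"required covariate {name!r} is missing")
            if self.covariates[name].isna().any():
                raise ValueError(f"covariate {name!r} has missing values")
        if self.group.isna().any():
            raise ValueError("group label missing for some subjects")
        levels = list(pd.unique(self.group))
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, found {levels}")
        counts = self.group.value_counts()
        if counts.min() < 4:
            raise ValueError(
                "each group needs >= 4 subjects for correlation degrees of "
                f"freedom, got {counts.to_dict()}"
            )
        if self.group_order is None:
            if {"patient", "control"} <= set(levels):
                self.group_order = ("patient", "control")
            else:
                self.group_order = tuple(sorted(levels))  # type: ignore[assignment]
        if set(self.group_order) != set(levels):
            raise ValueError(
                f"group_order {self.group_order} does not match labels {levels}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.thickness)

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]

    def group_mask(self, label: str) -> np.ndarray:
        if label not in self.group_order:
            raise KeyError(f"unknown group label {label!r}")
        return (self.group == label).to_numpy()

    def copy(self) -> "ThicknessDataset":
        return ThicknessDataset(
            self.thickness.copy(),
            self.covariates.copy(),
            self.group.copy(),
            self.atlas,
            self.group_order,
        )


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")


def _coerce_sex(series: pd.Series) -> pd.Series:
    def one(v):  # noqa: ANN001
        key = v.strip().lower() if isinstance(v, str) else v
        if isinstance(key, float) and key in (0.0, 1.0):
            key = int(key)
        if key not in _SEX_MAP:
            raise ValueError(
                f"sex value {v!r} not interpretable; expected male/female or 1/0"
            )
        return _SEX_MAP[key]

    coded = series.map(one).astype(int)
    logger.info("sex encoding: male=1, female=0 (input values mapped accordingly)")
    return coded


def read_thickness_table(
    path: str | Path,
    atlas: RegionAtlas,
    covariates_path: str | Path | None = None,
) -> ThicknessDataset:
    """Read a thickness table (and covariates) into a validated dataset.

    ``path`` holds a subject-id first column plus one column per atlas
    region; covariates (``group``, ``age``, ``sex``, ``tiv`` and any
    clinical scores) are taken from extra columns of the same file or from
    ``covariates_path``. Region columns are reordered to atlas order.
    Subjects missing any required covariate are dropped with a logged count.
    """
    path = Path(path)
    table = _read_delimited(path)

    missing = [r for r in atlas.region_id if r not in table.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing region column(s) {missing[:5]}"
            + ("" if len(missing) <= 5 else f" (+{len(missing) - 5} more)")
        )
    thickness = table[list(atlas.region_id)].apply(pd.to_numeric, errors="coerce")

    extra = table.drop(columns=list(atlas.region_id))
    if covariates_path is not None:
        cov_table = _read_delimited(Path(covariates_path))
        extra = extra.join(cov_table, how="left", rsuffix="_cov")

    if "group" not in extra.columns:
        raise ValueError("no 'group' column found in thickness or covariate file")
    for name in REQUIRED_COVARIATES:
        if name not in extra.columns:
            raise ValueError(f"required covariate column {name!r} not found")

    keep = extra[list(REQUIRED_COVARIATES)].notna().all(axis=1) & extra["group"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropping %d subject(s) with missing required covariates", n_dropped
        )
        thickness, extra = thickness[keep], extra[keep]

    group = extra["group"].astype(str)
    covariates = extra.drop(columns=["group"]).copy()
    covariates["sex"] = _coerce_sex(covariates["sex"])
    for name in ("age", "tiv"):
        covariates[name] = pd.to_numeric(covariates[name])

    return ThicknessDataset(thickness, covariates, group, atlas)


def write_thickness_table(ds: ThicknessDataset, path: str | Path) -> None:
    """Write a dataset as one merged delimited file (inverse of the reader)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    merged = pd.concat(
        [ds.group.rename("group"), ds.covariates, ds.thickness], axis=1
    )
    merged.index.name = "subject_id"
    merged.to_csv(path, sep=sep, encoding="utf-8")


def write_results_table(
    records: Iterable[Mapping] | pd.DataFrame, path: str | Path
) -> None:
    """Write metric/statistics rows as a TSV with a stable column order.

    Each record carries ``region_id`` (or ``"GLOBAL"``), ``metric``, the two
    group values, their difference, ``p`` and ``p_fdr``; extra keys are
    appended after the canonical columns in sorted order.
    """
    table = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else pd.DataFrame(list(records))
    )
    if table.empty:
        table = pd.DataFrame(columns=list(RESULT_COLUMNS))
    lead = [c for c in RESULT_COLUMNS if c in table.columns]
    rest = sorted(c for c in table.columns if c not in RESULT_COLUMNS)
    table = table[lead + rest]
    path = Path(path)
    try:
        table.to_csv(path, sep="\t", index=False, encoding="utf-8")
    except OSError as err:
        raise OSError(f"cannot write results table to {path}: {err}") from err
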