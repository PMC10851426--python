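"""Cortical parcellation atlas handling.

The node set of every structural covariance network is fixed by a
:class:`RegionAtlas`: an ordered list of region labels with hemisphere tags.
The bundled atlas is the standard 148-parcel sulco-gyral cortical
parcellation (74 regions per hemisphere). Atlas order is the single source
of node indexing — every downstream matrix is aligned against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

__all__ = ["RegionAtlas", "load_destrieux_atlas", "infer_atlas"]

_DESTRIEUX_FILE = "destrieux_regions.tsv"
_VALID_HEMIS = frozenset({"left", "right"})


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered cortical region list fixing the node indexing of all networks.

    Parameters
    ----------
    region_id :
        Unique region labels, in node-index order.
    hemisphere :
        ``"left"`` or ``"right"`` per region, aligned with ``region_id``.
    """

    region_id: tuple[str, ...]
    hemisphere: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.region_id) != len(self.hemisphere):
            raise ValueError("region_id and hemisphere must have equal length")
        if len(set(self.region_id)) != len(self.region_id):
            raise ValueError("region_id values must be unique")
        bad = set(self.hemisphere) - _VALID_HEMIS
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")
        object.__setattr__(
            self, "_index", {r: i for i, r in enumerate(self.region_id)}
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def index_of(self, region: str) -> int:
        """0-based node index of ``region``; KeyError if unknown."""
        return self._index[region]

    def __contains__(self, region: str) -> bool:
        return region in self._index

    def __len__(self) -> int:
        return len(self.region_id)

    def hemisphere_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"left": 0, "right": 0}
        for h in self.hemisphere:
            counts[h] += 1
        return counts

    def subset(self, n: int) -> "RegionAtlas":
        """First ``n`` regions, preserving order (for reduced-size cohorts)."""
        if not 1 <= n <= self.n_regions:
            raise ValueError(f"n must be in [1, {self.n_regions}], got {n}")
        return RegionAtlas(self.region_id[:n], self.hemisphere[:n])


def infer_atlas(columns: "Sequence[str]") -> RegionAtlas:
    """Infer the atlas that a table's columns were written against.

    Recognises the full bundled 148-region list, a leading subset of it
    (reduced-size cohorts), or generator-style synthetic region labels.
    """
    cols = set(columns)
    full = load_destrieux_atlas()
    present = [r for r in full.region_id if r in cols]
    if present:
        if present != list(full.region_id[: len(present)]):
            raise ValueError(
                "region columns are not a leading subset of the bundled atlas"
            )
        return full if len(present) == full.n_regions else full.subset(len(present))
    synth = sorted(c for c in cols if c.startswith("synth_region_"))
    if synth:
        hemis = tuple("left" if i % 2 == 0 else "right" for i in range(len(synth)))
        return RegionAtlas(tuple(synth), hemis)
    raise ValueError("no recognisable region columns found")


def load_destrieux_atlas() -> RegionAtlas:
    """Load the bundled 148-region sulco-gyral cortical atlas.

    Returns an atlas with exactly 148 regions, 74 tagged ``left`` and 74
    tagged ``right``, in a stable documented order (all left-hemisphere
    regions first). The list ships with the package as a TSV data file.
    """
    ref = resources.files("scnkit").joinpath("data", _DESTRIEUX_FILE)
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, sep="\t")
    if list(table.columns) != ["region_id", "hemisphere"]:
        raise ValueError(
            f"bundled atlas file {_DESTRIEUX_FILE} is corrupted: "
            f"unexpected columns {list(table.columns)}"
        )
    atlas = RegionAtlas(
        tuple(table["region_id"].astype(str)),
        tuple(table["hemisphere"].astype(str)),
    )
    counts = atlas.hemisphere_counts()
    if atlas.n_regions != 148 or counts["left"] != 74 or counts["right"] != 74:
        raise ValueError(
            "bundled atlas file is corrupted: expected 148 regions "
            f"(74 per hemisphere), found {atlas.n_regions} ({counts})"
        )
    return atlas
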