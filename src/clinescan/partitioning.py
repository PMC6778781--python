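"""Categorical sample partitions for the allele-frequency differentiation scans.

Each partition assigns every sample to exactly one group or excludes it.
Boundary conventions: numeric intervals are closed on their lower bound and
open on the upper ([1500, 3000) etc.), 48 degrees E falls in the eastern
group, and the wild-range latitude band is closed on both ends ([30, 40]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PartitionError(ValueError):
    """A partition could not be formed (e.g., an empty group)."""


@dataclass
class Partition:
    """Grouping of samples for one comparison.

    ``assignment`` maps sample_id -> group name; excluded samples are absent.
    """

    comparison_id: str
    levels: list[str]
    assignment: pd.Series

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        for level in self.levels:
            if counts.get(level, 0) == 0:
                raise PartitionError(
                    f"{self.comparison_id}: group '{level}' is empty"
                )
        extra = set(counts.index) - set(self.levels)
        if extra:
            raise PartitionError(f"{self.comparison_id}: unknown groups {extra}")

    @property
    def n_assigned(self) -> int:
        return len(self.assignment)

    def group_sizes(self) -> dict[str, int]:
        vc = self.assignment.value_counts()
        return {lv: int(vc.get(lv, 0)) for lv in self.levels}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.assignment.index,
                "comparison_id": self.comparison_id,
                "group": self.assignment.values,
            }
        )


def _build(comparison_id: str, levels: list[str], ids, groups) -> Partition:
    assignment = pd.Series(groups, index=ids).dropna()
    return Partition(comparison_id, levels, assignment)


def partition_elevation(meta: pd.DataFrame, mode: str = "two_level") -> Partition:
    """Elevation partition: 3,000 m threshold, or three bands split at
    1,500 m and 3,000 m.  Missing elevation -> excluded."""
    elev = pd.to_numeric(meta["elevation"], errors="coerce")
    if mode == "two_level":
        levels = ["low_elevation", "high_elevation"]
        groups = np.where(elev >= 3000, "high_elevation", "low_elevation")
        groups = np.where(elev.isna(), None, groups)
        return _build("elevation", levels, meta["sample_id"], groups)
    if mode == "three_level":
        levels = ["low_elevation", "mid_elevation", "high_elevation"]
        groups = np.select(
            [elev < 1500, (elev >= 1500) & (elev < 3000), elev >= 3000],
            levels,
            default=None,
        )
        return _build("elevation3", levels, meta["sample_id"], groups)
    raise ValueError(f"unknown mode {mode!r}")


def partition_latitude(meta: pd.DataFrame, side: str = "high") -> Partition:
    """Latitude partitions around the wild range of the species ([30, 40] N).

    ``side='high'``: wild range vs > 40 N; ``side='low'``: wild range vs
    < 30 N; ``side='three_level'``: all three bands.
    """
    lat = pd.to_numeric(meta["latitude"], errors="coerce")
    in_wild = (lat >= 30) & (lat <= 40)
    if side == "high":
        levels = ["wild_range", "high_latitude"]
        groups = np.select([in_wild, lat > 40], levels, default=None)
        return _build("high_latitude", levels, meta["sample_id"], groups)
    if side == "low":
        levels = ["wild_range", "low_latitude"]
        groups = np.select([in_wild, lat < 30], levels, default=None)
        return _build("low_latitude", levels, meta["sample_id"], groups)
    if side == "three_level":
        levels = ["low_latitude", "wild_range", "high_latitude"]
        groups = np.select([lat < 30, in_wild, lat > 40], levels, default=None)
        return _build("latitude3", levels, meta["sample_id"], groups)
    raise ValueError(f"unknown side {side!r}")


def partition_longitude(meta: pd.DataFrame) -> Partition:
    """East/west split at 48 degrees E (48.0 assigned east)."""
    lon = pd.to_numeric(meta["longitude"], errors="coerce")
    groups = np.select([lon < 48, lon >= 48], ["west", "east"], default=None)
    return _build("longitude", ["west", "east"], meta["sample_id"], groups)


def partition_growth_habit(meta: pd.DataFrame) -> Partition:
    """Spring vs winter growth habit; facultative and unknown excluded."""
    habit = meta["growth_habit"].astype(str)
    groups = np.select(
        [habit == "spring", habit == "winter"], ["spring", "winter"], default=None
    )
    return _build("growth_habit", ["spring", "winter"], meta["sample_id"], groups)


def standard_partitions(meta: pd.DataFrame) -> list[Partition]:
    """The five two-level comparisons used in the differentiation scan."""
    return [
        partition_elevation(meta, "two_level"),
        partition_latitude(meta, "high"),
        partition_latitude(meta, "low"),
        partition_longitude(meta),
        partition_growth_habit(meta),
    ]
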