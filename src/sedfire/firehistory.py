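"""Composite fire chronologies from tree-level fire-scar records.

A crossdated fire-scar sample contributes a recording span (inner to outer
ring year, calendar AD) and a set of dated scar years, each with an
intra-ring position (dormant .. latewood) indicating burn seasonality. A
site composite keeps only years in which at least ``min_trees`` trees were
scarred while at least ``min_depth`` trees were in recording status —
filtering out single-tree wounds. Fire return intervals are the first
differences of composite fire years, summarized by their median within a
stated period (inclusive bounds).

By default a tree is "recording" in every year of its [inner, outer] span;
the alternative convention that a tree records only from its first scar
onward ("recorder rule") is available via ``recording="post_first_scar"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "SCAR_POSITIONS",
    "TreeRecord",
    "FireScarDataset",
    "CompositeFireHistory",
    "sample_depth",
    "composite",
    "return_intervals",
    "median_fri",
    "seasonality_summary",
]

SCAR_POSITIONS = (
    "dormant",
    "early-earlywood",
    "middle-earlywood",
    "late-earlywood",
    "latewood",
    "unknown",
)


@dataclass(frozen=True)
class TreeRecord:
    """One tree: recording span and dated scars with intra-ring positions."""

    tree_id: str
    species: str  # e.g. PSME, PILA, PIPO, CHLA
    inner_year: int
    outer_year: int
    scars: Mapping[int, str]  # year AD -> position

    def __post_init__(self) -> None:
        if self.inner_year > self.outer_year:
            raise InputError(f"{self.tree_id}: inner year after outer year")
        for year, pos in self.scars.items():
            if not (self.inner_year <= year <= self.outer_year):
                raise InputError(
                    f"{self.tree_id}: scar year {year} outside span "
                    f"[{self.inner_year}, {self.outer_year}]"
                )
            if pos not in SCAR_POSITIONS:
                raise InputError(f"{self.tree_id}: unknown scar position {pos!r}")

    def recording_years(self, convention: str = "span") -> range:
        if convention == "span":
            return range(self.inner_year, self.outer_year + 1)
        if convention == "post_first_scar":
            if not self.scars:
                return range(0)
            return range(min(self.scars), self.outer_year + 1)
        raise InputError(f"unknown recording convention {convention!r}")


@dataclass(frozen=True)
class FireScarDataset:
    """A site's collection of fire-scarred trees."""

    trees: tuple[TreeRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trees", tuple(self.trees))
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate tree ids")

    def all_scars(self) -> list[tuple[str, int, str]]:
        return [(t.tree_id, y, p) for t in self.trees for y, p in sorted(t.scars.items())]


@dataclass(frozen=True)
class CompositeFireHistory:
    """Site-level fire-year chronology after threshold filtering."""

    fire_years: tuple[int, ...]  # sorted AD
    trees_scarred: Mapping[int, int]  # per fire year
    depth: Mapping[int, int]  # sample depth per fire year
    min_trees: int
    min_depth: int
    recording: str = "span"


def sample_depth(dataset: FireScarDataset, year: int, recording: str = "span") -> int:
    """Number of trees in recording status in *year*."""
    return sum(year in t.recording_years(recording) for t in dataset.trees)


def composite(
    dataset: FireScarDataset,
    min_trees: int = 2,
    min_depth: int = 2,
    recording: str = "span",
) -> CompositeFireHistory:
    """Fire years scarred by >= *min_trees* trees with sample depth >=
    *min_depth*; ``(1, 1)`` reproduces the unfiltered all-scars chronology."""
    if min_trees < 1 or min_depth < 1:
        raise InputError("thresholds must be >= 1")
    scarred: dict[int, int] = {}
    for t in dataset.trees:
        for year in t.scars:
            scarred[year] = scarred.get(year, 0) + 1
    fire_years = sorted(
        y for y, k in scarred.items()
        if k >= min_trees and sample_depth(dataset, y, recording) >= min_depth
    )
    return CompositeFireHistory(
        fire_years=tuple(fire_years),
        trees_scarred={y: scarred[y] for y in fire_years},
        depth={y: sample_depth(dataset, y, recording) for y in fire_years},
        min_trees=min_trees,
        min_depth=min_depth,
        recording=recording,
    )


def return_intervals(
    history: CompositeFireHistory,
    period: tuple[int, int] | None = None,
) -> list[int]:
    """First differences of consecutive composite fire years, restricted to
    fire years inside *period* (AD, inclusive). Empty with < 2 fire years."""
    years = history.fire_years
    if period is not None:
        lo, hi = min(period), max(period)
        years = tuple(y for y in years if lo <= y <= hi)
    return [b - a for a, b in zip(years, years[1:])]


def median_fri(
    history: CompositeFireHistory,
    period: tuple[int, int] | None = None,
) -> float | None:
    """Median fire return interval in years, or None when no interval exists
    (fewer than two composite fire years in the period)."""
    intervals = return_intervals(history, period)
    if not intervals:
        return None
    return float(np.median(intervals))


def seasonality_summary(dataset: FireScarDataset) -> dict:
    """Fractions of scars per intra-ring position among scars with a known
    position; unknowns are tallied separately and excluded from the
    denominator. Reports the combined latewood+dormant fraction — the
    late-season burn signature."""
    counts = {pos: 0 for pos in SCAR_POSITIONS}
    for _, _, pos in dataset.all_scars():
        counts[pos] += 1
    n_unknown = counts.pop("unknown")
    n_known = sum(counts.values())
    if n_known == 0:
        warnings.warn("no scars with known intra-ring position", stacklevel=2)
        return {"fractions": None, "latewood_dormant_fraction": None,
                "n_known": 0, "n_unknown": n_unknown}
    fractions = {pos: k / n_known for pos, k in counts.items()}
    return {
        "fractions": fractions,
        "latewood_dormant_fraction": fractions["latewood"] + fractions["dormant"],
        "n_known": n_known,
        "n_unknown": n_unknown,
    }
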