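"""Composite land-use intensity (LUI) index for managed grassland plots.

Each plot-year is described by three management components: fertilization
intensity ``F`` (kg N ha^-1 yr^-1), mowing frequency ``M`` (cuts yr^-1) and
grazing intensity ``G`` (livestock-unit grazing days ha^-1 yr^-1). The index
standardizes each component by its regional mean and applies a square-root
transform to even out the distribution:

    LUI_i = sqrt(F_i/F_R + M_i/M_R + G_i/G_R)

A plot's LUI over a multi-year interval is the arithmetic mean of its yearly
indices (the alternative — square root of the mean standardized components —
is available via ``aggregate="components"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "LandUseRecord",
    "RegionMeans",
    "region_means",
    "lui_index",
    "mean_lui",
    "read_records",
    "write_lui",
]

_COMPONENTS = ("F", "M", "G")


@dataclass(frozen=True)
class LandUseRecord:
    """One plot-year of land-use components (all non-negative)."""

    plot_id: str
    year: int
    F: float
    M: float
    G: float

    def __post_init__(self) -> None:
        for name in _COMPONENTS:
            value = getattr(self, name)
            if value < 0:
                raise ValueError(
                    f"{name}={value} for plot {self.plot_id!r}, year {self.year}: "
                    "land-use components must be non-negative"
                )


@dataclass(frozen=True)
class RegionMeans:
    """Regional means of the three components; each must be positive."""

    F_R: float
    M_R: float
    G_R: float

    def __post_init__(self) -> None:
        for name in ("F_R", "M_R", "G_R"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"regional mean {name} must be strictly positive "
                    f"(got {getattr(self, name)}); the index divides by it"
                )


def _check_unique(records: list[LandUseRecord]) -> None:
    seen = set()
    for rec in records:
        key = (rec.plot_id, rec.year)
        if key in seen:
            raise ValueError(f"duplicate land-use record for plot {key[0]!r}, year {key[1]}")
        seen.add(key)


def region_means(records: Iterable[LandUseRecord]) -> RegionMeans:
    """Component means pooled over every (plot, year) record.

    Raises if the record set is empty or any component averages to zero
    (a component never used anywhere in the region cannot standardize).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot compute regional means from an empty record set")
    _check_unique(records)
    means = {}
    for name in _COMPONENTS:
        mean = sum(getattr(r, name) for r in records) / len(records)
        if mean == 0:
            raise ValueError(
                f"regional mean of component {name} is zero; "
                "LUI standardization would divide by zero"
            )
        means[name] = mean
    return RegionMeans(F_R=means["F"], M_R=means["M"], G_R=means["G"])


def lui_index(record: LandUseRecord, means: RegionMeans) -> float:
    """Square-root of the sum of mean-standardized components for one plot-year."""
    total = record.F / means.F_R + record.M / means.M_R + record.G / means.G_R
    return total**0.5


def mean_lui(
    records: Iterable[LandUseRecord],
    means: RegionMeans,
    year_from: int,
    year_to: int,
    aggregate: str = "indices",
) -> pd.Series:
    """Per-plot mean LUI over the year interval ``[year_from, year_to]``.

    Parameters
    ----------
    aggregate:
        ``"indices"`` (default) averages the yearly square-root indices;
        ``"components"`` averages the standardized component sums first and
        takes a single square root.

    Returns a Series indexed by plot_id, named ``"LUI"``, sorted by plot.
    """
    if aggregate not in ("indices", "components"):
        raise ValueError(f"unknown aggregation mode {aggregate!r}")
    records = list(records)
    _check_unique(records)
    in_window = [r for r in records if year_from <= r.year <= year_to]
    all_plots = sorted({r.plot_id for r in records})
    by_plot: dict[str, list[LandUseRecord]] = {}
    for rec in in_window:
        by_plot.setdefault(rec.plot_id, []).append(rec)
    missing = [p for p in all_plots if p not in by_plot]
    if missing:
        raise ValueError(
            f"no land-use records in {year_from}-{year_to} for plot(s): {', '.join(missing)}"
        )
    values = {}
    for plot, recs in by_plot.items():
        if aggregate == "indices":
            values[plot] = sum(lui_index(r, means) for r in recs) / len(recs)
        else:
            sums = [
                r.F / means.F_R + r.M / means.M_R + r.G / means.G_R for r in recs
            ]
            values[plot] = (sum(sums) / len(sums)) ** 0.5
    out = pd.Series(values, name="LUI").sort_index()
    out.index.name = "plot_id"
    return out


def read_records(path) -> list[LandUseRecord]:
    """Read land-use records from a TSV with columns plot_id, year, F, M, G."""
    df = pd.read_csv(path, sep="\t", dtype={"plot_id": str})
    required = ["plot_id", "year", "F", "M", "G"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"land-use TSV {path} missing column(s): {', '.join(missing)}")
    return [
        LandUseRecord(
            plot_id=row.plot_id, year=int(row.year), F=float(row.F), M=float(row.M), G=float(row.G)
        )
        for row in df.itertuples(index=False)
    ]


def write_lui(lui: pd.Series, path) -> None:
    """Write a per-plot LUI table as TSV (plot_id, LUI)."""
    lui.rename("LUI").to_csv(path, sep="\t", header=True, index_label="plot_id")
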