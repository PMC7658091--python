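"""Occurrence records versus modelled suitability.

Citizen-science observation points are overlaid on the Ecoclimatic Index
grid and summarised as the fraction of records falling in suitable
(EI > 5) and highly suitable (EI > 15) cells — an explicit quantitative
surrogate for the graphical record-versus-map comparison usual in this
kind of validation.  Records landing on masked (water) cells are snapped
to the nearest land cell within one cell width, a concession to the
coordinate jitter typical of citizen-science data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_io import ClimateDataError
from .core_engine import ResultGrid
from .suitability_analysis import HIGHLY_SUITABLE_EI, SUITABLE_EI

__all__ = ["OccurrenceRecord", "OverlapReport", "read_occurrences", "write_occurrences", "overlap_statistics"]

DEFAULT_YEAR_RANGE = (2004, 2019)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced, verified observation."""

    lon: float
    lat: float
    year: int
    stage: str = ""
    source: str = ""


class OccurrenceFormatError(ValueError):
    """Malformed occurrence file or record."""


def read_occurrences(
    path,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
    strict: bool = False,
) -> list[OccurrenceRecord]:
    """Read occurrence records from CSV (headers lon, lat, year[, stage, source]).

    Rows with unparseable coordinates or a year outside ``year_range`` are
    skipped with a warning naming the offending line, or raise when
    ``strict`` is set.
    """
    import warnings

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"lon", "lat", "year"}
    missing = required - set(df.columns)
    if missing:
        raise OccurrenceFormatError(f"occurrence CSV is missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            lon, lat, year = float(row["lon"]), float(row["lat"]), int(row["year"])
            if not (np.isfinite(lon) and np.isfinite(lat)):
                raise ValueError("non-finite coordinates")
            if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                raise ValueError(f"coordinates out of range: lon={lon}, lat={lat}")
            if not (year_range[0] <= year <= year_range[1]):
                raise ValueError(f"year {year} outside {year_range[0]}-{year_range[1]}")
        except (ValueError, TypeError) as exc:
            msg = f"line {line}: {exc}"
            if strict:
                raise OccurrenceFormatError(msg) from exc
            warnings.warn(f"skipping occurrence record, {msg}")
            continue
        def _text(key: str) -> str:
            val = row.get(key, "")
            return "" if pd.isna(val) else str(val)

        records.append(
            OccurrenceRecord(lon=lon, lat=lat, year=year,
                             stage=_text("stage"), source=_text("source"))
        )
    return records


def write_occurrences(records: list[OccurrenceRecord], path) -> None:
    # %.17g keeps coordinate round-trips lossless
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, index=False, float_format="%.17g"
    )


@dataclass
class OverlapReport:
    """Record-versus-suitability overlap summary."""

    n_records: int
    n_in_bounds: int
    fraction_suitable: float
    fraction_highly_suitable: float
    per_year: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "year": ["all"],
                "n_records": [self.n_in_bounds],
                "fraction_suitable": [self.fraction_suitable],
                "fraction_highly_suitable": [self.fraction_highly_suitable],
            }
        )
        return pd.concat([head, self.per_year], ignore_index=True)


def _locate(grid: ResultGrid, lon: float, lat: float) -> tuple[int, int] | None:
    """Half-open cell assignment with one-cell snapping off water; None if outside."""
    d = grid.cell_size
    j = int(np.floor((lon - (grid.lon[0] - d / 2.0)) / d))
    i = int(np.floor((lat - (grid.lat[0] - d / 2.0)) / d))
    if not (0 <= j < grid.lon.size and 0 <= i < grid.lat.size):
        return None
    if grid.land_mask[i, j]:
        return i, j
    best, best_dist = None, np.inf
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = i + di, j + dj
            if 0 <= ii < grid.lat.size and 0 <= jj < grid.lon.size and grid.land_mask[ii, jj]:
                dist = np.hypot(grid.lon[jj] - lon, grid.lat[ii] - lat)
                if dist < best_dist and dist <= d:
                    best, best_dist = (ii, jj), dist
    return best


def overlap_statistics(
    records: list[OccurrenceRecord],
    grid: ResultGrid,
    thresholds: tuple[float, float] = (SUITABLE_EI, HIGHLY_SUITABLE_EI),
    grids_by_year: dict[int, ResultGrid] | None = None,
) -> OverlapReport:
    """Fractions of records in suitable / highly suitable cells.

    Each record is assigned to its containing cell on ``grid`` (or, per
    year, on the matching entry of ``grids_by_year`` when supplied, as
    when validating individual years against year-specific climate).
    Out-of-bounds records are counted separately and excluded from the
    fractions.
    """
    lo, hi = thresholds
    if hi < lo:
        raise ValueError("thresholds must be (low, high)")
    rows = []
    for rec in records:
        g = grid if grids_by_year is None else grids_by_year.get(rec.year, grid)
        loc = _locate(g, rec.lon, rec.lat)
        if loc is None:
            rows.append((rec.year, False, False, False))
            continue
        EI = g.EI[loc]
        rows.append((rec.year, True, EI > lo, EI > hi))
    df = pd.DataFrame(rows, columns=["year", "in_bounds", "suitable", "highly_suitable"])
    inb = df[df["in_bounds"]]
    if len(inb) == 0:
        raise ClimateDataError("no occurrence records fall inside the grid")
    per_year = (
        inb.groupby("year")
        .agg(
            n_records=("suitable", "size"),
            fraction_suitable=("suitable", "mean"),
            fraction_highly_suitable=("highly_suitable", "mean"),
        )
        .reset_index()
    )
    return OverlapReport(
        n_records=len(records),
        n_in_bounds=len(inb),
        fraction_suitable=float(inb["suitable"].mean()),
        fraction_highly_suitable=float(inb["highly_suitable"].mean()),
        per_year=per_year,
    )
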