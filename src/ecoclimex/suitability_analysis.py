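"""Summary products on top of the per-cell engine results.

Suitability classes (EI thresholds 1 / 5 / 15), area percentages over all
land cells, voltinism areas (cells supporting one or two generations),
per-location tables across scenarios, and phenology windows/shifts of the
weekly growth index.

The module also ships the reported Swiss area percentages for the 2-km
national assessment of *H. halys* (reference period 1981-2010, individual
years 2015-2019, and the CH2011 scenarios RCP3PD/A1B/A2 for three future
periods) so fold changes between scenario and reference suitable areas
can be computed without access to the proprietary input climatology, plus
the ten standard Swiss reference locations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_io import ClimateDataError, LocationQuery, cell_index
from .core_engine import AnnualCellResult, ResultGrid, _growth_window

__all__ = [
    "SuitabilitySummary",
    "AnalysisError",
    "classify_suitability",
    "area_percentages",
    "location_table",
    "phenology_window",
    "phenology_shift",
    "plot_map",
    "swiss_reference_locations",
    "swiss_reported_area_percentages",
    "suitable_area_fold_change",
]

CATEGORIES = ("unsuitable", "marginal", "suitable", "highly_suitable")
SUITABLE_EI = 5.0
HIGHLY_SUITABLE_EI = 15.0
SURVIVAL_EI = 1.0


class AnalysisError(ValueError):
    """Degenerate or inconsistent analysis input."""


@dataclass(frozen=True)
class SuitabilitySummary:
    """Area percentages over all counted cells (alpine cells included)."""

    pct_suitable: float
    pct_highly_suitable: float
    pct_one_gen: float
    pct_two_gen: float
    n_cells: int

    def to_dict(self) -> dict[str, float]:
        return {
            "pct_suitable": self.pct_suitable,
            "pct_highly_suitable": self.pct_highly_suitable,
            "pct_one_gen": self.pct_one_gen,
            "pct_two_gen": self.pct_two_gen,
            "n_cells": self.n_cells,
        }


def classify_suitability(EI):
    """Suitability category from the Ecoclimatic Index.

    unsuitable for EI < 1 (the species cannot survive), marginal for
    1 <= EI <= 5, suitable for 5 < EI <= 15, highly_suitable for EI > 15.
    The 5 and 15 cutoffs are strict.
    """
    EI = np.asarray(EI, dtype=float)
    cat = np.full(EI.shape, "unsuitable", dtype=object)
    cat[EI >= SURVIVAL_EI] = "marginal"
    cat[EI > SUITABLE_EI] = "suitable"
    cat[EI > HIGHLY_SUITABLE_EI] = "highly_suitable"
    if cat.ndim == 0:
        return str(cat[()])
    return cat


def area_percentages(result: ResultGrid, mask: np.ndarray | None = None) -> SuitabilitySummary:
    """Percentages of (highly) suitable and uni/bivoltine-capable cells.

    The denominator is every land cell, climatically impossible alpine
    cells included; pass ``mask`` to restrict the count to a sub-region.
    """
    counted = result.land_mask if mask is None else (result.land_mask & mask)
    n = int(counted.sum())
    if n == 0:
        raise AnalysisError("no cells to summarize")
    EI = result.EI[counted]
    gens = result.generations[counted]
    return SuitabilitySummary(
        pct_suitable=100.0 * float((EI > SUITABLE_EI).sum()) / n,
        pct_highly_suitable=100.0 * float((EI > HIGHLY_SUITABLE_EI).sum()) / n,
        pct_one_gen=100.0 * float((gens >= 1.0).sum()) / n,
        pct_two_gen=100.0 * float((gens >= 2.0).sum()) / n,
        n_cells=n,
    )


def location_table(
    grids: dict[str, ResultGrid],
    queries: list[LocationQuery],
    round_for_presentation: bool = True,
) -> pd.DataFrame:
    """EI, generations and growth weeks per location x scenario.

    ``grids`` maps scenario labels to result grids on a common layout.
    Presentation rounding (EI to integer, generations to 2 decimals,
    weeks to integer) matches the conventional tabulation; disable it to
    keep full precision.
    """
    rows = []
    for q in queries:
        row: dict[str, object] = {"location": q.name, "lon": q.lon, "lat": q.lat}
        for label, grid in grids.items():
            i, j = cell_index(grid, q.lon, q.lat)
            if not grid.land_mask[i, j]:
                raise ClimateDataError(
                    f"location {q.name!r} falls on a masked cell in {label!r}"
                )
            EI = grid.EI[i, j]
            gens = grid.generations[i, j]
            weeks = grid.growth_weeks[i, j]
            if round_for_presentation:
                EI, gens, weeks = int(round(EI)), round(gens, 2), int(weeks)
            row[f"EI {label}"] = EI
            row[f"generations {label}"] = gens
            row[f"growth_weeks {label}"] = weeks
        rows.append(row)
    columns = ["location", "lon", "lat"] + [
        f"{v} {label}" for label in grids for v in ("EI", "generations", "growth_weeks")
    ]
    return pd.DataFrame(rows, columns=columns)


def phenology_window(GI_w) -> tuple[int, int, int]:
    """(first_week, last_week, growth_weeks) of positive weekly growth.

    First/last are 1-based calendar weeks of the first and last week with
    GI_w > 0; mid-season zero dips are ignored (the window is the span of
    activity, not a run of consecutive positive weeks).
    """
    GI_w = np.asarray(GI_w, dtype=float)
    if GI_w.shape != (52,):
        raise AnalysisError("weekly growth index series must have 52 values")
    growth_weeks, first, last = _growth_window(GI_w)
    if int(growth_weeks) == 0:
        raise AnalysisError("growth window undefined: GI_w is zero all year")
    return int(first), int(last), int(growth_weeks)


def phenology_shift(baseline_GI_w, scenario_GI_w) -> tuple[int, int]:
    """(spring_shift, autumn_shift) in weeks between two growth seasons.

    Positive spring shift means activity starts earlier under the
    scenario; positive autumn shift means it stops later.
    """
    b_first, b_last, _ = phenology_window(baseline_GI_w)
    s_first, s_last, _ = phenology_window(scenario_GI_w)
    return b_first - s_first, s_last - b_last


def plot_map(result: ResultGrid, layer: str = "EI", ax=None, **imshow_kwargs):
    """Quick-look map of one result layer (masked cells transparent).

    Returns the matplotlib Axes; pass ``ax`` to draw into an existing
    figure.  This is a convenience for inspection, not cartography.
    """
    import matplotlib.pyplot as plt

    if layer not in ResultGrid.LAYERS:
        raise AnalysisError(f"unknown layer {layer!r}")
    if ax is None:
        _, ax = plt.subplots()
    data = np.where(result.land_mask, getattr(result, layer), np.nan)
    d = result.cell_size
    extent = (
        result.lon[0] - d / 2, result.lon[-1] + d / 2,
        result.lat[0] - d / 2, result.lat[-1] + d / 2,
    )
    im = ax.imshow(data, origin="lower", extent=extent, aspect="auto",
                   **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, label=layer)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax


# ---------------------------------------------------------------------------
# packaged Swiss reference tables


def _data_path(name: str):
    return importlib.resources.files("ecoclimex").joinpath("data", name)


def swiss_reference_locations() -> list[LocationQuery]:
    """The ten standard Swiss reference locations (name, lon, lat)."""
    df = pd.read_csv(_data_path("swiss_locations.csv"))
    return [LocationQuery(r["name"], float(r.lon), float(r.lat)) for _, r in df.iterrows()]


def swiss_reported_area_percentages() -> pd.DataFrame:
    """Reported Swiss area percentages per scenario x period.

    Columns: scenario_id, period, pct_suitable (EI > 5),
    pct_highly_suitable (EI > 15), pct_one_gen, pct_two_gen; percentages
    of the n = 11,211 cells of the national 2-km grid.
    """
    return pd.read_csv(_data_path("swiss_area_percentages.csv"))


def suitable_area_fold_change(
    table: pd.DataFrame,
    scenario_id: str,
    period: str,
    column: str = "pct_suitable",
    reference: tuple[str, str] = ("reference", "1981-2010"),
) -> float:
    """Ratio of a scenario's area percentage to the reference period's."""
    def pick(sid: str, per: str) -> float:
        sel = table[(table["scenario_id"] == sid) & (table["period"] == per)]
        if len(sel) != 1:
            raise AnalysisError(f"no unique row for {sid} {per}")
        return float(sel[column].iloc[0])

    ref = pick(*reference)
    if ref == 0:
        raise AnalysisError("reference percentage is zero")
    return pick(scenario_id, period) / ref
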