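"""Weekly growth/stress engine and the annual Ecoclimatic Index (EI).

The model runs on a 52-week year.  For each cell it computes

* a temperature index TI_w and soil-moisture index MI_w (piecewise-linear
  trapezoids over the four-point responses DV0..DV3 and SM0..SM3),
* a binary diapause indicator DI_w driven by day length and temperature,
* the weekly growth index GI_w = TI_w * MI_w * DI_w and its annual mean
  GI_A = 100 * mean(GI_w),
* five stress accumulators (cold, heat, dry, wet, hot-wet), each a linear
  sum of weekly threshold exceedances scaled by its rate, capped at 100,
* degree days above DV0 and the implied number of generations
  (DD_annual / PDD),

and combines them into EI = GI_A * prod(1 - stress/100), gated to zero
when the year's degree days cannot complete one generation
(DD_annual < PDD).  Soil moisture comes from a single-bucket water
balance driven by weekly rain and a temperature/humidity evaporation
term, iterated to its 52-periodic steady state.

All functions are vectorized: weekly series have the week on axis 0 and
any number of trailing cell axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .climate_io import (
    DAYS_PER_WEEK,
    N_WEEKS,
    MonthlyClimateGrid,
    day_length,
    derive_relative_humidity,
    monthly_to_weekly_linear,
    monthly_to_weekly_precip,
)
from .species_params import SpeciesParameters, default_parameters

__all__ = [
    "EngineConfig",
    "WeeklyClimate",
    "AnnualCellResult",
    "ResultGrid",
    "temperature_index",
    "moisture_index",
    "weekly_evaporation",
    "soil_moisture_series",
    "diapause_series",
    "growth_index_series",
    "annual_growth_index",
    "stress_indices",
    "degree_days_annual",
    "ecoclimatic_index",
    "build_weekly_climate",
    "run_cell",
    "run_grid",
]

STRESS_NAMES = ("CS", "HS", "DS", "WS", "HW")


@dataclass(frozen=True)
class EngineConfig:
    """Engine settings not tied to the species.

    capacity_mm: soil bucket capacity (mm of water held at S = 1).
    k_e: evaporation coefficient (mm per degC per day at dry air).
    s_init: initial soil moisture fraction for the bucket spin-up.
    s_max: upper bound on stored moisture as a fraction of capacity.
        The default 1.0 is the classic single-bucket convention (water in
        excess of field capacity runs off).  Values above 1 represent
        ponding/saturated soil and make the wet and hot-wet moisture
        thresholds (1.5 for this species) reachable through the bucket.
    """

    capacity_mm: float = 100.0
    k_e: float = 0.8
    s_init: float = 0.5
    s_max: float = 1.0


@dataclass
class WeeklyClimate:
    """Weekly climate inputs for one or many cells (week on axis 0)."""

    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    daylength: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "rain", "rh09", "rh15", "daylength"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[0] != N_WEEKS:
                raise ValueError(f"{name} must have {N_WEEKS} weeks on axis 0")
            if np.isnan(arr).any():
                raise ValueError(f"{name} contains missing values")
            setattr(self, name, arr)
        if np.any(self.tmin > self.tmax):
            raise ValueError("tmin exceeds tmax")
        if np.any(self.rain < 0):
            raise ValueError("negative weekly rain")

    @property
    def tavg(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class AnnualCellResult:
    """Annual summary for one cell (or arrays of cells)."""

    GI_A: float
    CS: float
    HS: float
    DS: float
    WS: float
    HW: float
    SI: float
    DD_annual: float
    generations: float
    growth_weeks: int
    first_growth_week: int
    last_growth_week: int
    EI: float
    GI_w: np.ndarray | None = None

    def stresses(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in STRESS_NAMES}


# ---------------------------------------------------------------------------
# index functions


def _trapezoid(x, x0, x1, x2, x3):
    """0 outside (x0, x3), 1 on [x1, x2], linear ramps between."""
    x = np.asarray(x, dtype=float)
    up = (x - x0) / (x1 - x0)
    down = (x3 - x) / (x3 - x2)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def temperature_index(tavg, p: SpeciesParameters):
    """Weekly temperature suitability in [0, 1] from the DV0..DV3 response."""
    return _trapezoid(tavg, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(S, p: SpeciesParameters):
    """Weekly soil-moisture suitability in [0, 1] from the SM0..SM3 response."""
    return _trapezoid(S, p.SM0, p.SM1, p.SM2, p.SM3)


def weekly_evaporation(tavg, rh09, rh15, k_e: float = 0.8):
    """Weekly evaporative demand (mm) driving the soil bucket.

    A simple temperature/saturation-deficit form: zero at or below 0 degC
    and in saturated air, otherwise proportional to temperature and to the
    mean daytime relative-humidity deficit.
    """
    tavg = np.asarray(tavg, dtype=float)
    deficit = 1.0 - (np.asarray(rh09, float) + np.asarray(rh15, float)) / 200.0
    return k_e * DAYS_PER_WEEK * np.maximum(0.0, tavg) * np.maximum(0.0, deficit)


def soil_moisture_series(
    rain,
    evap,
    capacity: float = 100.0,
    S0: float = 0.5,
    s_max: float = 1.0,
    tol: float = 1e-9,
    max_passes: int = 20,
):
    """Single-bucket weekly soil moisture, iterated to a periodic steady state.

    Recurrence S_w = clip(S_{w-1} + (rain_w - evap_w)/capacity, 0, s_max).
    The 52-week loop is repeated (same forcing every pass) until the series
    changes by less than ``tol`` between passes, so the result is the
    climatological steady state rather than a spin-up transient.
    """
    rain = np.asarray(rain, dtype=float)
    evap = np.asarray(evap, dtype=float)
    if capacity <= 0:
        raise ValueError("bucket capacity must be positive")
    delta = (rain - evap) / capacity
    S = np.empty_like(delta)
    prev_state = np.broadcast_to(np.asarray(S0, dtype=float), delta.shape[1:]).copy()
    last = None
    for _ in range(max_passes):
        state = prev_state
        for w in range(N_WEEKS):
            state = np.clip(state + delta[w], 0.0, s_max)
            S[w] = state
        if last is not None and np.max(np.abs(S - last)) < tol:
            break
        last = S.copy()
        prev_state = state
    return S


def diapause_series(tavg, daylength, p: SpeciesParameters):
    """Binary weekly diapause indicator (1 = growing, 0 = dormant).

    Winter diapause: induced at the first week of the shortening-day half
    of the year with day length below DPD0 and mean temperature below
    DPT0; terminated at the first subsequent lengthening-day week with
    mean temperature above DPT1, after at least DPD days in diapause.
    The 52-week state machine is run twice so the reported year is the
    periodic steady state (a cell can enter the year already dormant).
    """
    if p.DPSW != 0:
        raise NotImplementedError("summer diapause (DPSW = 1) is not supported")
    tavg = np.asarray(tavg, dtype=float)
    daylength = np.asarray(daylength, dtype=float)
    tavg, daylength = np.broadcast_arrays(tavg, daylength)
    shortening = np.roll(daylength, -1, axis=0) - daylength < 0.0
    lengthening = np.roll(daylength, -1, axis=0) - daylength > 0.0

    shape = tavg.shape[1:]
    diap = np.zeros(shape, dtype=bool)
    days_in = np.zeros(shape, dtype=float)
    DI = np.ones_like(tavg)
    for cycle in range(2):
        for w in range(N_WEEKS):
            terminate = (
                diap
                & lengthening[w]
                & (tavg[w] > p.DPT1)
                & (days_in >= p.DPD)
            )
            diap = diap & ~terminate
            days_in = np.where(terminate, 0.0, days_in)
            induce = (
                ~diap
                & shortening[w]
                & (daylength[w] < p.DPD0)
                & (tavg[w] < p.DPT0)
            )
            diap = diap | induce
            days_in = np.where(diap, days_in + DAYS_PER_WEEK, days_in)
            if cycle == 1:
                DI[w] = np.where(diap, 0.0, 1.0)
    return DI


def growth_index_series(TI, MI, DI):
    """GI_w = TI_w * MI_w * DI_w, the weekly growth index in [0, 1]."""
    return np.asarray(TI, float) * np.asarray(MI, float) * np.asarray(DI, float)


def annual_growth_index(GI_w):
    """GI_A = 100 * mean weekly growth index, in [0, 100]."""
    GI_w = np.asarray(GI_w, dtype=float)
    return 100.0 * GI_w.sum(axis=0) / N_WEEKS


def stress_indices(tmin, tmax, tavg, S, p: SpeciesParameters):
    """Annual cold/heat/dry/wet/hot-wet stress, each in [0, 100].

    Each stress is a linear accumulation of weekly threshold exceedance at
    its published rate (stored negative rates contribute by magnitude),
    scaled to the 0-100 range and capped at 100.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    tavg = np.asarray(tavg, float)
    S = np.asarray(S, float)
    CS = 100.0 * abs(p.THCS) * np.maximum(0.0, p.TTCS - tmin).sum(axis=0)
    HS = 100.0 * p.THHS * np.maximum(0.0, tmax - p.TTHS).sum(axis=0)
    DS = 100.0 * abs(p.HDS) * np.maximum(0.0, p.SMDS - S).sum(axis=0)
    WS = 100.0 * p.HWS * np.maximum(0.0, S - p.SMWS).sum(axis=0)
    HW = 100.0 * p.PHW * (
        np.maximum(0.0, tavg - p.TTHW) * (S > p.MTHW)
    ).sum(axis=0)
    return tuple(np.minimum(100.0, x) for x in (CS, HS, DS, WS, HW))


def degree_days_annual(tavg, p: SpeciesParameters):
    """Annual degree days above DV0 and the implied generations per year.

    DD_w = 7 * max(0, tavg_w - DV0); generations = DD_annual / PDD
    (real-valued; integer-generation maps take the floor downstream).
    """
    tavg = np.asarray(tavg, dtype=float)
    DD = DAYS_PER_WEEK * np.maximum(0.0, tavg - p.DV0).sum(axis=0)
    return DD, DD / p.PDD


def ecoclimatic_index(GI_A, CS, HS, DS, WS, HW, DD_annual, p: SpeciesParameters):
    """EI = GI_A * stress survival product, gated by the thermal constant.

    The survival factor is prod(1 - stress/100) over the five stresses;
    a year whose degree days cannot complete one generation
    (DD_annual < PDD) is unsuitable outright (EI = 0).
    """
    GI_A = np.asarray(GI_A, dtype=float)
    SI = np.ones_like(GI_A)
    for s in (CS, HS, DS, WS, HW):
        SI = SI * (1.0 - np.asarray(s, float) / 100.0)
    EI = GI_A * SI
    EI = np.where(np.asarray(DD_annual, float) < p.PDD, 0.0, EI)
    return np.clip(EI, 0.0, 100.0)


# ---------------------------------------------------------------------------
# composition


def build_weekly_climate(tmin_m, tmax_m, prec_m, latitude) -> WeeklyClimate:
    """Weekly engine inputs from 12 monthly values (month on axis 0).

    Temperatures and the monthly-derived 09:00/15:00 relative humidities
    are interpolated to week midpoints; precipitation is disaggregated
    conservatively; day length follows from latitude alone.
    """
    tmin_m = np.asarray(tmin_m, dtype=float)
    tmax_m = np.asarray(tmax_m, dtype=float)
    rh09_m, rh15_m = derive_relative_humidity(tmin_m, tmax_m)
    tmin_w = monthly_to_weekly_linear(tmin_m)
    tmax_w = monthly_to_weekly_linear(tmax_m)
    # interpolation can nick the ordering when diurnal range varies; keep it
    tmax_w = np.maximum(tmin_w, tmax_w)
    return WeeklyClimate(
        tmin=tmin_w,
        tmax=tmax_w,
        rain=monthly_to_weekly_precip(np.asarray(prec_m, float)),
        rh09=np.minimum(100.0, monthly_to_weekly_linear(rh09_m)),
        rh15=np.minimum(100.0, monthly_to_weekly_linear(rh15_m)),
        daylength=day_length(np.asarray(latitude, dtype=float)),
    )


def _growth_window(GI_w):
    """(growth_weeks, first_week, last_week) with 1-based weeks, 0 if none."""
    GI_w = np.asarray(GI_w, dtype=float)
    active = GI_w > 0.0
    growth_weeks = active.sum(axis=0)
    weeks = np.arange(1, N_WEEKS + 1).reshape((N_WEEKS,) + (1,) * (GI_w.ndim - 1))
    first = np.where(active, weeks, N_WEEKS + 1).min(axis=0)
    last = np.where(active, weeks, 0).max(axis=0)
    first = np.where(growth_weeks > 0, first, 0)
    return growth_weeks, first, last


def _run_arrays(climate: WeeklyClimate, p: SpeciesParameters, config: EngineConfig):
    """Vectorized engine core: weekly arrays in, annual summary dict out."""
    tavg = climate.tavg
    evap = weekly_evaporation(tavg, climate.rh09, climate.rh15, k_e=config.k_e)
    S = soil_moisture_series(
        climate.rain, evap,
        capacity=config.capacity_mm, S0=config.s_init, s_max=config.s_max,
    )
    TI = temperature_index(tavg, p)
    MI = moisture_index(S, p)
    DI = diapause_series(tavg, climate.daylength, p)
    GI_w = growth_index_series(TI, MI, DI)
    GI_A = annual_growth_index(GI_w)
    CS, HS, DS, WS, HW = stress_indices(climate.tmin, climate.tmax, tavg, S, p)
    DD, gens = degree_days_annual(tavg, p)
    EI = ecoclimatic_index(GI_A, CS, HS, DS, WS, HW, DD, p)
    SI = np.ones_like(GI_A)
    for s in (CS, HS, DS, WS, HW):
        SI = SI * (1.0 - s / 100.0)
    growth_weeks, first, last = _growth_window(GI_w)
    return {
        "GI_A": GI_A, "CS": CS, "HS": HS, "DS": DS, "WS": WS, "HW": HW,
        "SI": SI, "DD_annual": DD, "generations": gens,
        "growth_weeks": growth_weeks, "first_growth_week": first,
        "last_growth_week": last, "EI": EI, "GI_w": GI_w, "S": S,
    }


def run_cell(
    climate: WeeklyClimate,
    p: SpeciesParameters | None = None,
    config: EngineConfig | None = None,
) -> AnnualCellResult:
    """Run the full engine on one cell's 52-week climate."""
    p = p or default_parameters()
    config = config or EngineConfig()
    for name in ("tmin", "tmax", "rain", "rh09", "rh15", "daylength"):
        if np.asarray(getattr(climate, name)).ndim != 1:
            raise ValueError("run_cell expects scalar (1-D) weekly series")
    out = _run_arrays(climate, p, config)
    return AnnualCellResult(
        GI_A=float(out["GI_A"]),
        CS=float(out["CS"]), HS=float(out["HS"]), DS=float(out["DS"]),
        WS=float(out["WS"]), HW=float(out["HW"]), SI=float(out["SI"]),
        DD_annual=float(out["DD_annual"]),
        generations=float(out["generations"]),
        growth_weeks=int(out["growth_weeks"]),
        first_growth_week=int(out["first_growth_week"]),
        last_growth_week=int(out["last_growth_week"]),
        EI=float(out["EI"]),
        GI_w=out["GI_w"],
    )


@dataclass
class ResultGrid:
    """Per-cell annual results on the input grid (NaN on masked cells)."""

    lon: np.ndarray
    lat: np.ndarray
    land_mask: np.ndarray
    EI: np.ndarray
    GI_A: np.ndarray
    CS: np.ndarray
    HS: np.ndarray
    DS: np.ndarray
    WS: np.ndarray
    HW: np.ndarray
    DD_annual: np.ndarray
    generations: np.ndarray
    growth_weeks: np.ndarray
    first_growth_week: np.ndarray
    last_growth_week: np.ndarray
    elevation: np.ndarray | None = None

    LAYERS = (
        "EI", "GI_A", "CS", "HS", "DS", "WS", "HW",
        "DD_annual", "generations", "growth_weeks",
        "first_growth_week", "last_growth_week",
    )

    @property
    def cell_size(self) -> float:
        for axis in (self.lon, self.lat):
            if axis.size > 1:
                return float(np.diff(axis)[0])
        return 0.02

    def to_dataset(self):
        import xarray as xr

        coords = {"lat": ("lat", self.lat), "lon": ("lon", self.lon)}
        data = {k: (("lat", "lon"), getattr(self, k)) for k in self.LAYERS}
        data["land_mask"] = (("lat", "lon"), self.land_mask.astype(np.int8))
        if self.elevation is not None:
            data["elevation"] = (("lat", "lon"), self.elevation)
        return xr.Dataset(data, coords=coords)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table keyed by cell lon/lat, land cells only."""
        ii, jj = np.nonzero(self.land_mask)
        data = {"lon": self.lon[jj], "lat": self.lat[ii]}
        for k in self.LAYERS:
            data[k] = getattr(self, k)[ii, jj]
        if self.elevation is not None:
            data["elevation"] = self.elevation[ii, jj]
        return pd.DataFrame(data)

    def write(self, path) -> None:
        path = str(path)
        if path.endswith((".nc", ".nc4", ".cdf")):
            self.to_dataset().to_netcdf(path, engine="scipy")
        else:
            self.to_dataframe().to_csv(path, index=False)


def run_grid(
    grid: MonthlyClimateGrid,
    p: SpeciesParameters | None = None,
    config: EngineConfig | None = None,
) -> ResultGrid:
    """Run the engine on every land cell of a monthly grid.

    Converts monthly fields to weekly series per cell, runs the vectorized
    engine, and returns gridded annual layers with the input coordinates
    preserved; masked cells hold NaN.
    """
    p = p or default_parameters()
    config = config or EngineConfig()
    ii, jj = np.nonzero(grid.land_mask)
    if ii.size == 0:
        raise ValueError("grid has no land cells")
    lat_cells = grid.lat[ii]
    climate = build_weekly_climate(
        grid.tmin[:, ii, jj], grid.tmax[:, ii, jj], grid.prec[:, ii, jj],
        lat_cells,
    )
    out = _run_arrays(climate, p, config)

    nlat, nlon = grid.shape
    layers: dict[str, np.ndarray] = {}
    for k in ResultGrid.LAYERS:
        full = np.full((nlat, nlon), np.nan)
        full[ii, jj] = out[k]
        layers[k] = full
    return ResultGrid(
        lon=grid.lon, lat=grid.lat, land_mask=grid.land_mask.copy(),
        elevation=None if grid.elevation is None else grid.elevation.copy(),
        **layers,
    )
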