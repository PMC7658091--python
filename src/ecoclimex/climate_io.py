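"""Gridded monthly climate: containers, readers/writers, weekly conversion.

The engine runs on a 52-week year (exactly 364 days), while observational
climatologies come as 12 monthly values per cell (mean daily minimum and
maximum temperature, precipitation sum) on a regular latitude-longitude
grid.  This module holds the grid container and every derivation from
monthly inputs to weekly engine inputs:

* piecewise-linear interpolation of temperatures (and humidities) from
  month midpoints to week midpoints, with periodic wrap;
* exact-conservation disaggregation of monthly precipitation sums into
  weekly sums;
* relative humidity at 09:00 and 15:00 from the Magnus saturation vapour
  pressure, with dew point approximated by the daily minimum temperature;
* astronomical day length from solar declination;
* point-in-cell extraction of single locations.

Supported on-disk dialects: NetCDF (CF-style month/lat/lon dims) and a
long-format CSV (lon, lat, month, tmin, tmax, prec[, elevation]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MonthlyClimateGrid",
    "LocationQuery",
    "ClimateDataError",
    "read_monthly_grid",
    "write_monthly_grid",
    "monthly_to_weekly_linear",
    "monthly_to_weekly_precip",
    "saturation_vapour_pressure",
    "derive_relative_humidity",
    "day_length",
    "extract_location",
]

N_WEEKS = 52
DAYS_PER_WEEK = 7
#: day-of-year length of the weekly engine year (52 * 7)
WEEK_YEAR_DAYS = N_WEEKS * DAYS_PER_WEEK
#: calendar used for month anchors (non-leap)
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
CAL_YEAR_DAYS = float(MONTH_DAYS.sum())  # 365
_MONTH_EDGES = np.concatenate([[0.0], np.cumsum(MONTH_DAYS)])
#: day-of-year of each month's midpoint
MONTH_MIDPOINTS = _MONTH_EDGES[:-1] + MONTH_DAYS / 2.0
#: day-of-year of each week's midpoint on the 364-day year
WEEK_MIDPOINTS = np.arange(N_WEEKS) * DAYS_PER_WEEK + DAYS_PER_WEEK / 2.0


class ClimateDataError(ValueError):
    """Malformed, inconsistent or physically impossible climate input."""


@dataclass
class LocationQuery:
    """A named point to extract from a grid (WGS84 degrees)."""

    name: str
    lon: float
    lat: float


@dataclass
class MonthlyClimateGrid:
    """Monthly climatology on a regular lon/lat grid.

    Arrays are indexed ``[month, lat, lon]`` (month 0..11); ``lon`` and
    ``lat`` are ascending cell-center coordinates in WGS84 degrees with
    constant spacing.  ``land_mask`` marks the cells the engine runs on.
    """

    lon: np.ndarray
    lat: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    elevation: np.ndarray | None = None
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        for name in ("tmin", "tmax", "prec"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)
        if self.land_mask is None:
            self.land_mask = np.ones((self.lat.size, self.lon.size), dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.validate()

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def n_cells(self) -> int:
        """Number of land cells."""
        return int(self.land_mask.sum())

    @property
    def cell_size(self) -> float:
        for axis in (self.lon, self.lat):
            if axis.size > 1:
                return float(np.diff(axis)[0])
        return 0.02

    def validate(self) -> None:
        nlat, nlon = self.lat.size, self.lon.size
        expected = (12, nlat, nlon)
        for name in ("tmin", "tmax", "prec"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ClimateDataError(
                    f"{name} has shape {arr.shape}, expected {expected}"
                )
        for axis, label in ((self.lon, "lon"), (self.lat, "lat")):
            if axis.size > 1:
                d = np.diff(axis)
                if d.min() <= 0:
                    raise ClimateDataError(f"{label} coordinates must be ascending")
                if np.ptp(d) > 1e-9:
                    raise ClimateDataError(f"{label} spacing is not constant")
        land = self.land_mask
        bad = (self.tmin > self.tmax) & land
        if bad.any():
            m, i, j = (int(x[0]) for x in np.nonzero(bad))
            raise ClimateDataError(
                f"tmin > tmax at lon={self.lon[j]:.4f}, lat={self.lat[i]:.4f}, "
                f"month={m + 1}"
            )
        if ((self.prec < 0) & land).any():
            raise ClimateDataError("negative precipitation")
        if ((np.abs(self.tmin) > 60) & land).any() or (
            (np.abs(self.tmax) > 60) & land
        ).any():
            raise ClimateDataError("temperature outside the physical range [-60, 60]")
        if ((self.prec > 5000) & land).any():
            raise ClimateDataError("precipitation above 5000 mm/month")

    # -- xarray / disk -----------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "month": np.arange(1, 13),
            "lat": ("lat", self.lat),
            "lon": ("lon", self.lon),
        }
        data = {
            "tmin": (("month", "lat", "lon"), self.tmin),
            "tmax": (("month", "lat", "lon"), self.tmax),
            "prec": (("month", "lat", "lon"), self.prec),
            "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
        }
        if self.elevation is not None:
            data["elevation"] = (("lat", "lon"), self.elevation)
        ds = xr.Dataset(data, coords=coords)
        ds["tmin"].attrs["units"] = "degC"
        ds["tmax"].attrs["units"] = "degC"
        ds["prec"].attrs["units"] = "mm/month"
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "MonthlyClimateGrid":
        for var in ("tmin", "tmax", "prec"):
            if var not in ds:
                raise ClimateDataError(f"dataset is missing variable {var!r}")
        return cls(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            tmin=ds["tmin"].values,
            tmax=ds["tmax"].values,
            prec=ds["prec"].values,
            elevation=ds["elevation"].values if "elevation" in ds else None,
            land_mask=ds["land_mask"].values.astype(bool) if "land_mask" in ds else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (one row per land cell x month)."""
        nlat, nlon = self.shape
        ii, jj = np.nonzero(self.land_mask)
        rows = []
        for m in range(12):
            df = pd.DataFrame(
                {
                    "lon": self.lon[jj],
                    "lat": self.lat[ii],
                    "month": m + 1,
                    "tmin": self.tmin[m, ii, jj],
                    "tmax": self.tmax[m, ii, jj],
                    "prec": self.prec[m, ii, jj],
                }
            )
            if self.elevation is not None:
                df["elevation"] = self.elevation[ii, jj]
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["lat", "lon", "month"], ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MonthlyClimateGrid":
        required = {"lon", "lat", "month", "tmin", "tmax", "prec"}
        missing = required - set(df.columns)
        if missing:
            raise ClimateDataError(f"CSV is missing columns: {sorted(missing)}")
        lon = np.unique(df["lon"].to_numpy(float))
        lat = np.unique(df["lat"].to_numpy(float))
        nlat, nlon = lat.size, lon.size
        jj = np.searchsorted(lon, df["lon"].to_numpy(float))
        ii = np.searchsorted(lat, df["lat"].to_numpy(float))
        mm = df["month"].to_numpy(int) - 1
        if mm.min() < 0 or mm.max() > 11:
            raise ClimateDataError("month must be in 1..12")
        tmin = np.full((12, nlat, nlon), np.nan)
        tmax = np.full((12, nlat, nlon), np.nan)
        prec = np.full((12, nlat, nlon), np.nan)
        tmin[mm, ii, jj] = df["tmin"].to_numpy(float)
        tmax[mm, ii, jj] = df["tmax"].to_numpy(float)
        prec[mm, ii, jj] = df["prec"].to_numpy(float)
        present = ~np.isnan(tmin).any(axis=0)
        partial = present ^ ~np.isnan(tmin).all(axis=0)
        if partial.any():
            i, j = (int(x[0]) for x in np.nonzero(partial))
            raise ClimateDataError(
                f"cell lon={lon[j]:.4f}, lat={lat[i]:.4f} has an incomplete "
                "12-month record"
            )
        elevation = None
        if "elevation" in df.columns:
            elevation = np.zeros((nlat, nlon))
            elevation[ii, jj] = df["elevation"].to_numpy(float)
        # water/off-grid cells carry benign filler so validation can vectorize
        for arr, fill in ((tmin, 0.0), (tmax, 0.0), (prec, 0.0)):
            arr[:, ~present] = fill
        return cls(
            lon=lon, lat=lat, tmin=tmin, tmax=tmax, prec=prec,
            elevation=elevation, land_mask=present,
        )


def read_monthly_grid(path: str | Path, format: str | None = None) -> MonthlyClimateGrid:
    """Read a monthly grid from NetCDF (``.nc``) or long-format CSV."""
    path = Path(path)
    if not path.exists():
        raise ClimateDataError(f"no such climate file: {path}")
    fmt = format or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            return MonthlyClimateGrid.from_dataset(ds.load())
    if fmt == "csv":
        return MonthlyClimateGrid.from_dataframe(
            pd.read_csv(path, float_precision="round_trip")
        )
    raise ClimateDataError(f"unknown climate format: {fmt!r}")


def write_monthly_grid(
    grid: MonthlyClimateGrid, path: str | Path, format: str | None = None
) -> None:
    """Write a grid in the same dialects ``read_monthly_grid`` accepts."""
    path = Path(path)
    fmt = format or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "netcdf":
        grid.to_dataset().to_netcdf(path, engine="scipy")
    elif fmt == "csv":
        grid.to_dataframe().to_csv(path, index=False)
    else:
        raise ClimateDataError(f"unknown climate format: {fmt!r}")


# ---------------------------------------------------------------------------
# monthly -> weekly conversion


def _interp_weights() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing month indices and weights for each week midpoint (periodic)."""
    mids = np.concatenate(
        [[MONTH_MIDPOINTS[-1] - CAL_YEAR_DAYS], MONTH_MIDPOINTS,
         [MONTH_MIDPOINTS[0] + CAL_YEAR_DAYS]]
    )
    idx = np.searchsorted(mids, WEEK_MIDPOINTS, side="right") - 1
    x0, x1 = mids[idx], mids[idx + 1]
    w1 = (WEEK_MIDPOINTS - x0) / (x1 - x0)
    m0 = (idx - 1) % 12
    m1 = idx % 12
    return m0, m1, w1


_M0, _M1, _W1 = _interp_weights()

# precipitation disaggregation: overlap of week w and month m in days,
# normalized by month length so each month's total is conserved exactly
_week_lo = np.arange(N_WEEKS) * DAYS_PER_WEEK
_week_hi = _week_lo + DAYS_PER_WEEK
_week_hi[-1] = CAL_YEAR_DAYS  # final week absorbs the 364/365 mismatch
_overlap = np.maximum(
    0.0,
    np.minimum(_week_hi[:, None], _MONTH_EDGES[None, 1:])
    - np.maximum(_week_lo[:, None], _MONTH_EDGES[None, :-1]),
)
PRECIP_WEIGHTS = _overlap / MONTH_DAYS[None, :]  # (52, 12); columns sum to 1


def monthly_to_weekly_linear(values: np.ndarray) -> np.ndarray:
    """Interpolate 12 monthly values to 52 weekly values.

    Piecewise-linear between month midpoints (day-of-year anchors of a
    365-day calendar), sampled at week midpoints of the 364-day engine
    year, with periodic wrap across the year boundary.  The month axis
    must be first; trailing axes (cells) pass through.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != 12:
        raise ClimateDataError("monthly series must have 12 values on axis 0")
    w1 = _W1.reshape((N_WEEKS,) + (1,) * (values.ndim - 1))
    return (1.0 - w1) * values[_M0] + w1 * values[_M1]


def monthly_to_weekly_precip(prec: np.ndarray) -> np.ndarray:
    """Disaggregate 12 monthly sums to 52 weekly sums, conserving the total.

    Each month's sum is split across weeks proportionally to the number of
    that month's days falling in each week; the 52nd week absorbs the one
    leftover calendar day so the annual total is conserved exactly.
    """
    prec = np.asarray(prec, dtype=float)
    if prec.shape[0] != 12:
        raise ClimateDataError("monthly series must have 12 values on axis 0")
    return np.tensordot(PRECIP_WEIGHTS, prec, axes=(1, 0))


# ---------------------------------------------------------------------------
# humidity and day length


def saturation_vapour_pressure(T):
    """Magnus saturation vapour pressure over water (hPa), T in degC."""
    T = np.asarray(T, dtype=float)
    return 6.112 * np.exp(17.62 * T / (243.12 + T))


def derive_relative_humidity(tmin, tmax):
    """Morning (09:00) and afternoon (15:00) relative humidity (%) from
    daily temperature extremes.

    Assumes dew point ~= daily minimum, so the actual vapour pressure is
    e_s(tmin); air temperature at 09:00 and 15:00 sits at fixed fractions
    (0.4 and 0.9) of the diurnal range above tmin.  Returns values in
    (0, 100], saturated when the diurnal range vanishes.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    e_a = saturation_vapour_pressure(tmin)
    t09 = tmin + 0.4 * (tmax - tmin)
    t15 = tmin + 0.9 * (tmax - tmin)
    rh09 = np.minimum(100.0, 100.0 * e_a / saturation_vapour_pressure(t09))
    rh15 = np.minimum(100.0, 100.0 * e_a / saturation_vapour_pressure(t15))
    return rh09, rh15


def day_length(latitude, week=None):
    """Astronomical day length (hours) at the middle day of each week.

    Standard solar-declination formula; valid equatorward of the polar
    circles (|latitude| <= 66.5).  ``week`` is 1..52 (scalar or array);
    omitted, all 52 weeks are returned on a leading axis.
    """
    latitude = np.asarray(latitude, dtype=float)
    if np.any(np.abs(latitude) > 66.5):
        raise ClimateDataError("latitudes poleward of 66.5 deg are not supported")
    if week is None:
        doy = WEEK_MIDPOINTS.reshape((N_WEEKS,) + (1,) * latitude.ndim)
    else:
        doy = (np.asarray(week, dtype=float) - 1) * DAYS_PER_WEEK + DAYS_PER_WEEK / 2.0
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    x = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(decl), -1.0, 1.0)
    return (24.0 / np.pi) * np.arccos(x)


# ---------------------------------------------------------------------------
# location extraction


def cell_index(grid: MonthlyClimateGrid, lon: float, lat: float) -> tuple[int, int]:
    """(lat, lon) indices of the cell whose half-open box contains the point.

    Cell membership is [center - d/2, center + d/2): a point on the shared
    edge of two cells belongs to the higher-coordinate cell's lower edge,
    i.e. the lower-left cell keeps its own lower edge only.
    """
    d = grid.cell_size
    j = int(np.floor((lon - (grid.lon[0] - d / 2.0)) / d))
    i = int(np.floor((lat - (grid.lat[0] - d / 2.0)) / d))
    if not (0 <= j < grid.lon.size and 0 <= i < grid.lat.size):
        raise ClimateDataError(
            f"point lon={lon}, lat={lat} is outside the grid bounding box"
        )
    return i, j


def extract_location(grid: MonthlyClimateGrid, query: LocationQuery) -> pd.DataFrame:
    """Monthly series of the grid cell containing the query point.

    Returns a 12-row frame (month, tmin, tmax, prec) with the cell-center
    coordinates attached as attrs.  Raises on out-of-bounds or water cells.
    """
    i, j = cell_index(grid, query.lon, query.lat)
    if not grid.land_mask[i, j]:
        raise ClimateDataError(
            f"query {query.name!r} falls on a masked (water) cell at "
            f"lon={grid.lon[j]:.4f}, lat={grid.lat[i]:.4f}"
        )
    df = pd.DataFrame(
        {
            "month": np.arange(1, 13),
            "tmin": grid.tmin[:, i, j],
            "tmax": grid.tmax[:, i, j],
            "prec": grid.prec[:, i, j],
        }
    )
    df.attrs["name"] = query.name
    df.attrs["cell_lon"] = float(grid.lon[j])
    df.attrs["cell_lat"] = float(grid.lat[i])
    if grid.elevation is not None:
        df.attrs["elevation"] = float(grid.elevation[i, j])
    return df
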