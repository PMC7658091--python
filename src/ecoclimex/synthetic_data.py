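"""Switzerland-like synthetic inputs: climate grids, change signals, records.

The generator emulates an alpine country on a regular 0.02 degree grid:

* topography built from smooth Gaussian ridges (a lower northern range
  and a higher southern massif) over a warm valley floor;
* monthly temperature from a sea-level annual mean with a sinusoidal
  seasonal cycle, an elevational lapse rate and small Gaussian noise;
* monthly precipitation scaled to the cell's evaporative demand (plus a
  base amount and an optional orographic term) so that soil moisture sits
  at field capacity and is non-limiting — the moisture regime observed
  for this species in temperate alpine climates, where suitability is
  set by temperature alone;
* occurrence records sampled from climatically suitable cells with
  within-cell jitter.

Everything is deterministic given the seed.  The default extent is a
20 x 15 cell desk-scale grid; the ``swiss_size`` preset has 101 x 111 =
11,211 cells, the size of the national 2-km climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .climate_io import MONTH_DAYS, MonthlyClimateGrid, derive_relative_humidity
from .core_engine import ResultGrid
from .scenarios import ChangeSignal
from .validation import OccurrenceRecord

__all__ = [
    "SyntheticConfig",
    "swiss_size_config",
    "make_synthetic_grid",
    "make_change_signal",
    "default_scenario_suite",
    "sample_occurrences",
]

MONTH_INDEX = np.arange(1, 13)
#: seasonal cycle peaking in July, zero-mean over the year
SEASONAL_SHAPE = np.cos(2.0 * np.pi * (MONTH_INDEX - 7) / 12.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic alpine climate generator.

    Temperatures in degC, elevations in m, precipitation in mm/month.
    ``sea_level_temp`` and ``seasonal_amplitude`` put the valley floor
    (~250 m) at an annual mean near 11.4 degC with January around 2.4 and
    July around 20.4 degC — a north-alpine lowland; ``lapse_rate`` cools
    the ridges (top ~2300 m, annual mean near -2 degC).  ``moisture_ratio``
    scales precipitation to that multiple of the cell's evaporative
    demand (2.0 keeps the soil bucket at field capacity year-round).
    """

    n_lon: int = 20
    n_lat: int = 15
    cell_size: float = 0.02
    lon0: float = 7.0
    lat0: float = 46.4
    valley_floor_m: float = 250.0
    ridge_amplitude_m: float = 2000.0
    terrain_noise_sd_m: float = 25.0
    sea_level_temp: float = 13.0
    seasonal_amplitude: float = 9.0
    lapse_rate: float = -6.5
    diurnal_range: float = 8.0
    moisture_ratio: float = 2.0
    precip_base: float = 10.0
    orographic_factor: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


def swiss_size_config(seed: int = 0) -> SyntheticConfig:
    """Preset with 101 x 111 = 11,211 cells (national 2-km grid size)."""
    return SyntheticConfig(n_lon=101, n_lat=111, seed=seed)


def _terrain(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Two smooth diagonal ridges over a valley floor, in metres."""
    u = np.linspace(0.0, 1.0, cfg.n_lon)[None, :]
    v = np.linspace(0.0, 1.0, cfg.n_lat)[:, None]
    if cfg.n_lon == 1:
        u = np.full_like(u, 0.5)
    if cfg.n_lat == 1:
        v = np.full_like(v, 0.5)
    northern = 0.45 * np.exp(-(((v - (0.22 + 0.15 * u)) / 0.10) ** 2))
    southern = 1.00 * np.exp(-(((v - (0.78 - 0.08 * u)) / 0.16) ** 2))
    relief = np.minimum(1.0, northern + southern)
    noise = rng.normal(0.0, cfg.terrain_noise_sd_m, size=relief.shape)
    return np.maximum(0.0, cfg.valley_floor_m + cfg.ridge_amplitude_m * relief + noise)


def _monthly_evaporative_demand(tmin_m, tmax_m, k_e: float = 0.8) -> np.ndarray:
    """Monthly evaporation estimate (mm) matching the engine's weekly form."""
    tmean = 0.5 * (tmin_m + tmax_m)
    rh09, rh15 = derive_relative_humidity(tmin_m, tmax_m)
    deficit = np.maximum(0.0, 1.0 - (rh09 + rh15) / 200.0)
    days = MONTH_DAYS.reshape((12,) + (1,) * (tmean.ndim - 1))
    return k_e * days * np.maximum(0.0, tmean) * deficit


def make_synthetic_grid(config: SyntheticConfig | None = None) -> MonthlyClimateGrid:
    """Generate a synthetic alpine monthly climate grid (with elevation)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    elev = _terrain(cfg, rng)
    lon = cfg.lon0 + cfg.cell_size * np.arange(cfg.n_lon)
    lat = cfg.lat0 + cfg.cell_size * np.arange(cfg.n_lat)

    shape = (12, cfg.n_lat, cfg.n_lon)
    tmean = (
        cfg.sea_level_temp
        + cfg.seasonal_amplitude * SEASONAL_SHAPE[:, None, None]
        + cfg.lapse_rate * elev[None, :, :] / 1000.0
        + rng.normal(0.0, cfg.noise_sd, size=shape)
    )
    tmin = tmean - cfg.diurnal_range / 2.0
    tmax = tmean + cfg.diurnal_range / 2.0
    prec = (
        cfg.moisture_ratio * _monthly_evaporative_demand(tmin, tmax)
        + cfg.precip_base
        + cfg.orographic_factor * elev[None, :, :] / 1000.0
    )
    return MonthlyClimateGrid(
        lon=lon, lat=lat, tmin=tmin, tmax=tmax, prec=prec, elevation=elev
    )


def make_change_signal(
    scenario_id: str, period: str, dT_annual: float, dP_annual: float = 0.0
) -> ChangeSignal:
    """Uniform monthly change signal with a mild seasonal cycle.

    Warming is summer-weighted and precipitation change summer-
    accentuated (drying for negative annual deltas); monthly values are
    scaled so their annual means equal the requested deltas exactly, and
    a zero request yields an all-zero signal.
    """
    if dP_annual <= -100:
        raise ValueError("dP_annual must stay above -100%")
    shape = 1.0 + 0.3 * SEASONAL_SHAPE
    return ChangeSignal(scenario_id, period, dT_annual * shape, dP_annual * shape)


def default_scenario_suite() -> list[ChangeSignal]:
    """Nine illustrative scenario x period signals (three emission paths,
    three future periods), with warming and mild summer drying increasing
    from the stabilisation path to the strongest non-intervention path."""
    spec = {
        "RCP3PD": {"2020-2049": (1.2, -2.0), "2045-2074": (1.4, -2.0), "2070-2099": (1.5, -3.0)},
        "A1B": {"2020-2049": (1.4, -3.0), "2045-2074": (2.6, -5.0), "2070-2099": (3.6, -7.0)},
        "A2": {"2020-2049": (1.3, -3.0), "2045-2074": (2.5, -5.0), "2070-2099": (4.1, -8.0)},
    }
    return [
        make_change_signal(sid, period, dT, dP)
        for sid, periods in spec.items()
        for period, (dT, dP) in periods.items()
    ]


def sample_occurrences(
    result: ResultGrid,
    n: int,
    seed: int = 0,
    year_range: tuple[int, int] = (2004, 2019),
) -> list[OccurrenceRecord]:
    """Sample occurrence points from climatically suitable cells.

    Cells are drawn with probability proportional to max(0, EI - 5), the
    point is jittered uniformly within the cell, and years are uniform
    over ``year_range``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    EI = np.where(result.land_mask, np.nan_to_num(result.EI), 0.0)
    weights = np.maximum(0.0, EI - 5.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("no cells with EI > 5 to sample occurrences from")
    cells = rng.choice(weights.size, size=n, p=weights / total)
    ii, jj = np.unravel_index(cells, EI.shape)
    d = result.cell_size
    lon = result.lon[jj] + rng.uniform(-d / 2.0, d / 2.0, size=n)
    lat = result.lat[ii] + rng.uniform(-d / 2.0, d / 2.0, size=n)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    return [
        OccurrenceRecord(float(lon[k]), float(lat[k]), int(years[k]), source="synthetic")
        for k in range(n)
    ]
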