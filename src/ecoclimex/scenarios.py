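"""Delta-change construction of future climate grids.

Future climate is built by perturbing the observed monthly baseline with a
change signal: monthly temperature deltas (degC) are added to both the
daily minimum and maximum temperature (leaving the diurnal range
unchanged), and monthly precipitation deltas (%) scale the precipitation
sum multiplicatively.  Interannual variability is untouched by
construction.  Relative humidity is re-derived downstream from the
perturbed temperatures, so a scenario run needs no extra humidity input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_io import ClimateDataError, MonthlyClimateGrid

__all__ = ["ChangeSignal", "apply_deltas", "read_change_signals", "write_change_signals"]


@dataclass
class ChangeSignal:
    """Monthly change signal for one scenario x period combination.

    dT: 12 monthly temperature deltas (degC), uniform (shape (12,)) or
    per-cell (shape (12, nlat, nlon)).  dP: 12 monthly precipitation
    deltas in percent, same shape options; dP must stay above -100.
    """

    scenario_id: str
    period: str
    dT: np.ndarray
    dP: np.ndarray

    def __post_init__(self) -> None:
        self.dT = np.asarray(self.dT, dtype=float)
        self.dP = np.asarray(self.dP, dtype=float)
        for name, arr in (("dT", self.dT), ("dP", self.dP)):
            if arr.shape[0] != 12:
                raise ClimateDataError(f"{name} must have 12 monthly values")
        if np.any(self.dP <= -100.0):
            raise ClimateDataError("precipitation deltas must stay above -100%")

    @property
    def label(self) -> str:
        return f"{self.scenario_id} {self.period}"

    @classmethod
    def zero(cls, scenario_id: str = "baseline", period: str = "") -> "ChangeSignal":
        return cls(scenario_id, period, np.zeros(12), np.zeros(12))


def _broadcast(name: str, arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if arr.ndim == 1:
        return arr[:, None, None]
    if arr.shape[1:] == shape:
        return arr
    raise ClimateDataError(
        f"{name} per-cell shape {arr.shape[1:]} does not match grid {shape}"
    )


def apply_deltas(baseline: MonthlyClimateGrid, signal: ChangeSignal) -> MonthlyClimateGrid:
    """Perturbed copy of the baseline grid under one change signal.

    tmin' = tmin + dT, tmax' = tmax + dT, prec' = prec * (1 + dP/100);
    coordinates, elevation and land mask are carried over unchanged, and
    all grid validation re-runs on the output.
    """
    dT = _broadcast("dT", signal.dT, baseline.shape)
    dP = _broadcast("dP", signal.dP, baseline.shape)
    return MonthlyClimateGrid(
        lon=baseline.lon.copy(),
        lat=baseline.lat.copy(),
        tmin=baseline.tmin + dT,
        tmax=baseline.tmax + dT,
        prec=baseline.prec * (1.0 + dP / 100.0),
        elevation=None if baseline.elevation is None else baseline.elevation.copy(),
        land_mask=baseline.land_mask.copy(),
    )


def read_change_signals(path: str | Path) -> list[ChangeSignal]:
    """Read uniform change signals from a long-format CSV.

    Columns: scenario_id, period, month (1..12), dT (degC), dP (%).
    One ChangeSignal per distinct scenario_id x period pair.
    """
    df = pd.read_csv(path)
    required = {"scenario_id", "period", "month", "dT", "dP"}
    missing = required - set(df.columns)
    if missing:
        raise ClimateDataError(f"signal CSV is missing columns: {sorted(missing)}")
    signals = []
    for (sid, period), sub in df.groupby(["scenario_id", "period"], sort=False):
        sub = sub.sort_values("month")
        if list(sub["month"]) != list(range(1, 13)):
            raise ClimateDataError(
                f"signal {sid} {period} must have exactly months 1..12"
            )
        signals.append(
            ChangeSignal(str(sid), str(period), sub["dT"].to_numpy(), sub["dP"].to_numpy())
        )
    return signals


def write_change_signals(signals: list[ChangeSignal], path: str | Path) -> None:
    rows = []
    for s in signals:
        if s.dT.ndim != 1:
            raise ClimateDataError("only uniform signals can be written as CSV")
        for m in range(12):
            rows.append(
                {"scenario_id": s.scenario_id, "period": s.period,
                 "month": m + 1, "dT": s.dT[m], "dP": s.dP[m]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
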