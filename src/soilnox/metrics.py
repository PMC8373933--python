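"""Ozone exposure metrics and photochemical-regime diagnostics.

Implements the three exposure metrics used for ozone air-quality assessment —
MDA8 (daily maximum 8-h running mean), NDGT70 (days with MDA8 strictly above
70 ppb) and AOT40 (accumulated daytime hourly exceedance over 40 ppb) — plus
the standard-condition unit conversion for network data reported in ug m^-3,
the H2O2/HNO3 ozone-formation-regime indicator, and ozone production
efficiency (OPE).

Completeness policy (configurable): an 8-h window needs at least 6 of its 8
hours; a day needs at least one valid window; MDA8 windows are confined to
the calendar day (start hours 00-16 local).  AOT40 daytime is 08:00-19:59
local.  All metrics operate in local time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import xarray as xr

# O3 conversion at 273.15 K, 1 atm: molar volume 22.414 L mol^-1, M(O3) = 48.00 g mol^-1
MOLAR_VOLUME_STP = 22.414
M_O3 = 48.00
M_N = 14.007
PPB_PER_UGM3 = MOLAR_VOLUME_STP / M_O3

MDA8_MIN_HOURS_PER_WINDOW = 6
AOT40_DAYTIME = (8, 20)  # [start, end) local hours
NDGT70_THRESHOLD = 70.0  # ppb, strict >


@dataclass
class StationSeries:
    """Hourly ozone record for one monitoring site, in local time.

    ``ozone`` is indexed by strictly increasing hourly timestamps; gaps are
    represented as NaN after :func:`regularize`.  ``units`` is ``"ppb"`` or
    ``"ugm3_stp"`` (ug m^-3 at 273.15 K, 1 atm, the reporting convention of
    the Chinese national monitoring network).
    """

    station_id: str
    ozone: pd.Series
    units: str = "ppb"

    def __post_init__(self):
        if self.units not in ("ppb", "ugm3_stp"):
            raise ValueError(f"units must be 'ppb' or 'ugm3_stp', got {self.units!r}")
        idx = self.ozone.index
        if len(idx) > 1:
            dt = np.diff(idx.view("i8"))
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, station_id: Optional[str] = None,
                   value_col: str = "o3_ugm3", units: str = "ugm3_stp") -> "StationSeries":
        if station_id is not None:
            df = df[df["station_id"] == station_id]
        else:
            station_id = str(df["station_id"].iloc[0])
        s = pd.Series(df[value_col].to_numpy(),
                      index=pd.DatetimeIndex(df["timestamp"]), name="o3")
        return cls(station_id=station_id, ozone=s, units=units)


def regularize(series: StationSeries) -> StationSeries:
    """Reindex onto a complete hourly grid spanning the record (gaps -> NaN)."""
    idx = series.ozone.index
    full = pd.date_range(idx[0].floor("h"), idx[-1].ceil("h"), freq="h")
    return replace(series, ozone=series.ozone.reindex(full))


def convert_ugm3_to_ppb(series: StationSeries) -> StationSeries:
    """Convert ug m^-3 at 273.15 K / 1 atm to ppb: multiply by 22.414 / 48.00."""
    if series.units != "ugm3_stp":
        raise ValueError("series is already in ppb; refusing to convert twice")
    return replace(series, ozone=series.ozone * PPB_PER_UGM3, units="ppb")


def qc_station_series(series: StationSeries, *, max_stuck_run: int = 24) -> StationSeries:
    """Basic quality control: drop negative values and stuck-instrument runs.

    Runs of >= ``max_stuck_run`` consecutive identical non-missing values are
    removed (instrument stuck); negatives become NaN.
    """
    s = series.ozone.copy()
    s[s < 0] = np.nan
    vals = s.to_numpy()
    n = len(vals)
    i = 0
    while i < n:
        if np.isnan(vals[i]):
            i += 1
            continue
        j = i + 1
        while j < n and vals[j] == vals[i]:
            j += 1
        if j - i >= max_stuck_run:
            vals[i:j] = np.nan
        i = j
    return replace(series, ozone=pd.Series(vals, index=s.index, name=s.name))


# ---------------------------------------------------------------------------
# MDA8
# ---------------------------------------------------------------------------

def _mda8_from_day_values(day_vals: np.ndarray,
                          min_hours: int = MDA8_MIN_HOURS_PER_WINDOW) -> float:
    """MDA8 from one calendar day's 24 hourly values (NaN = missing).

    Considers the 17 windows starting 00:00-16:00; each window mean uses the
    hours present and is valid with >= ``min_hours`` of 8; the day is valid
    with >= 1 valid window.
    """
    best = np.nan
    for start in range(17):
        w = day_vals[start:start + 8]
        nvalid = np.sum(~np.isnan(w))
        if nvalid >= min_hours:
            m = np.nanmean(w)
            if np.isnan(best) or m > best:
                best = m
    return best


def mda8_daily(series: StationSeries) -> pd.Series:
    """Daily MDA8 series, ppb, indexed by date; invalid days are NaN."""
    if series.units != "ppb":
        raise ValueError("mda8 expects a ppb series; convert units first")
    idx = series.ozone.index
    if ((idx.minute != 0) | (idx.second != 0)).any():
        raise ValueError("non-hourly cadence: timestamps must fall on whole hours")
    s = regularize(series).ozone
    out = {}
    for day, grp in s.groupby(s.index.normalize()):
        vals = np.full(24, np.nan)
        vals[grp.index.hour] = grp.to_numpy()
        out[day] = _mda8_from_day_values(vals)
    return pd.Series(out, name="mda8")


def mda8(series: StationSeries, day=None):
    """MDA8 for one day (if given) or the daily series."""
    daily = mda8_daily(series)
    if day is None:
        return daily
    return float(daily.loc[pd.Timestamp(day).normalize()])


def ndgt70(mda8_series: pd.Series, threshold: float = NDGT70_THRESHOLD) -> int:
    """Number of valid days with MDA8 strictly above the threshold (70 ppb)."""
    return int((mda8_series.dropna() > threshold).sum())


def aot40(series: StationSeries, daytime: Tuple[int, int] = AOT40_DAYTIME,
          cutoff: float = 40.0) -> float:
    """Accumulated daytime hourly exceedance over 40 ppb, in ppb h."""
    if series.units != "ppb":
        raise ValueError("aot40 expects a ppb series; convert units first")
    s = series.ozone
    day = (s.index.hour >= daytime[0]) & (s.index.hour < daytime[1])
    exc = (s[day] - cutoff).clip(lower=0.0)
    return float(np.nansum(exc.to_numpy()))


def metrics_table(series: StationSeries) -> pd.Series:
    """MDA8 mean, NDGT70, AOT40 and valid-day count for one station record."""
    daily = mda8_daily(series)
    return pd.Series({
        "station_id": series.station_id,
        "mda8_mean": float(daily.mean(skipna=True)),
        "ndgt70": ndgt70(daily),
        "aot40": aot40(series),
        "valid_day_count": int(daily.notna().sum()),
    })


# ---------------------------------------------------------------------------
# gridded metrics (time, lat, lon DataArrays in ppb, local time)
# ---------------------------------------------------------------------------

def mda8_grid(o3: xr.DataArray) -> xr.DataArray:
    """Daily MDA8 on a gridded hourly field; requires complete 24 h days."""
    time = pd.DatetimeIndex(o3.time.values)
    nt = len(time)
    if nt % 24 != 0:
        raise ValueError("gridded MDA8 requires whole 24 h days")
    arr = o3.transpose("time", ...).values
    nd = nt // 24
    daily = arr.reshape((nd, 24) + arr.shape[1:])
    # 17 within-day windows of 8 h
    win = np.stack([daily[:, s:s + 8].mean(axis=1) for s in range(17)], axis=1)
    m = win.max(axis=1)
    days = time.normalize()[::24]
    dims = ("time",) + tuple(d for d in o3.dims if d != "time")
    coords = {d: o3.coords[d] for d in dims if d != "time"}
    coords["time"] = days
    return xr.DataArray(m, dims=dims, coords=coords, name="mda8",
                        attrs={"units": "ppb"})


def ndgt70_grid(mda8_field: xr.DataArray, threshold: float = NDGT70_THRESHOLD) -> xr.DataArray:
    """Per-cell count of days with MDA8 > threshold."""
    return (mda8_field > threshold).sum("time").rename("ndgt70")


def aot40_grid(o3: xr.DataArray, daytime: Tuple[int, int] = AOT40_DAYTIME,
               cutoff: float = 40.0) -> xr.DataArray:
    """Per-cell AOT40, ppb h, over the field's whole period."""
    hrs = pd.DatetimeIndex(o3.time.values).hour
    day = (hrs >= daytime[0]) & (hrs < daytime[1])
    exc = (o3.isel(time=np.where(day)[0]) - cutoff).clip(min=0.0)
    return exc.sum("time").rename("aot40")


# ---------------------------------------------------------------------------
# regime diagnostics
# ---------------------------------------------------------------------------

REGIME_NOX_SENSITIVE = "NOx-sensitive-leaning"
REGIME_NOX_SATURATED = "NOx-saturated/transitional"


def regime_indicator(h2o2, hno3, threshold: float = 1.0):
    """H2O2/HNO3 ratio and regime classification.

    Ratios above the threshold (default 1, regionally variable) lean
    NOx-sensitive; at or below they indicate a NOx-saturated or transitional
    regime.  Cells with zero HNO3 are masked (NaN ratio, empty class).
    """
    h2o2 = np.asarray(h2o2, dtype=float)
    hno3 = np.asarray(hno3, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hno3 > 0, h2o2 / hno3, np.nan)
    classes = np.where(np.isnan(ratio), "",
                       np.where(ratio > threshold, REGIME_NOX_SENSITIVE,
                                REGIME_NOX_SATURATED))
    if ratio.ndim == 0:
        return float(ratio), str(classes)
    return ratio, classes


def ozone_production_efficiency(delta_o3_mass_g: float,
                                delta_nox_mass_g_n: float) -> float:
    """Ozone molecules produced per molecule of NOx emitted.

    Both inputs are masses: ozone as g O3, NOx as g N (one N per NOx
    molecule, so moles of N equal moles of NOx).
    """
    if delta_nox_mass_g_n == 0:
        raise ValueError("delta NOx must be nonzero")
    return (delta_o3_mass_g / M_O3) / (delta_nox_mass_g_n / M_N)
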