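"""Hourly gridded soil NOx flux simulator (BDSNP).

The flux at each grid cell and hour is the product of a biome- and
nitrogen-dependent emission factor, a temperature response f(T), a soil
moisture response g(theta) over water-filled pore space, and a wetting-pulse
enhancement P that fires when a long-dry soil is rewetted:

    flux = [base(biome) + gamma * N_avail] * f(T) * g(theta) * P * (1 - CRF)

N_avail is the sum of a natural pool, a decaying fertilizer pool fed by the
application schedule, and an exogenous deposition pool.  The pulse amplitude
at wetting is ``13.01 * ln(l_dry) - 53.6`` with ``l_dry`` the antecedent dry
spell in hours; the pulse then decays as ``exp(-c t)`` and switches off once
the enhancement drops back to 1.  Dry spells shorter than about 62 h give an
amplitude below 1 and start no pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .params import BdsnpParams, ConfigError

NG_PER_TG = 1e21
SECONDS_PER_HOUR = 3600.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MetForcing:
    """Hourly gridded meteorological forcing for the emission model.

    soil_temperature : (nt, ny, nx) degC, top soil layer
    wfps             : (nt, ny, nx) water-filled pore space in [0, 1]
    arid_mask        : (ny, nx) bool
    biome_id         : (ny, nx) int, keys into the emission-factor tables
    """

    time: pd.DatetimeIndex
    soil_temperature: np.ndarray
    wfps: np.ndarray
    arid_mask: np.ndarray
    biome_id: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        if self.wfps.min() < 0 or self.wfps.max() > 1:
            raise ValueError("wfps must lie in [0, 1]")
        if self.soil_temperature.shape != self.wfps.shape:
            raise ValueError("soil_temperature and wfps shapes differ")

    @property
    def grid_shape(self):
        return self.arid_mask.shape

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "soil_temperature": (("time", "lat", "lon"), self.soil_temperature,
                                     {"units": "degC"}),
                "wfps": (("time", "lat", "lon"), self.wfps, {"units": "1"}),
                "arid_mask": (("lat", "lon"), self.arid_mask.astype("i1"), {"units": "1"}),
                "biome_id": (("lat", "lon"), self.biome_id.astype("i4"), {"units": "1"}),
            },
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "MetForcing":
        return cls(
            time=pd.DatetimeIndex(ds.time.values),
            soil_temperature=ds.soil_temperature.values,
            wfps=ds.wfps.values,
            arid_mask=ds.arid_mask.values.astype(bool),
            biome_id=ds.biome_id.values.astype(int),
            lat=ds.lat.values,
            lon=ds.lon.values,
        )


@dataclass
class FertilizerSchedule:
    """Daily nitrogen application per cell, kg N ha^-1 day^-1."""

    days: pd.DatetimeIndex
    application: np.ndarray  # (n_days, ny, nx)

    def annual_total(self) -> np.ndarray:
        return self.application.sum(axis=0)

    def for_date(self, date) -> np.ndarray:
        date = pd.Timestamp(date).normalize()
        idx = self.days.get_indexer([date])[0]
        if idx < 0:
            return np.zeros(self.application.shape[1:])
        return self.application[idx]

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"application": (("time", "lat", "lon"), self.application,
                             {"units": "kg N ha-1 d-1"})},
            coords={"time": self.days,
                    "lat": np.arange(self.application.shape[1], dtype=float),
                    "lon": np.arange(self.application.shape[2], dtype=float)},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "FertilizerSchedule":
        return cls(days=pd.DatetimeIndex(ds.time.values), application=ds.application.values)


@dataclass
class SoilCellState:
    """Per-cell nitrogen pools and pulse state, advanced hourly.

    All fields are arrays over the grid; pools in kg N ha^-1, clocks in hours.
    """

    n_natural: np.ndarray
    n_fert: np.ndarray
    n_dep: np.ndarray
    l_dry: np.ndarray
    pulse_active: np.ndarray     # bool
    pulse_elapsed: np.ndarray    # h since the wetting that started the pulse
    pulse_amplitude: np.ndarray  # dimensionless, >= 1 while active

    @classmethod
    def zeros(cls, shape, n_natural=0.0, n_dep=0.0) -> "SoilCellState":
        return cls(
            n_natural=np.full(shape, float(n_natural)),
            n_fert=np.zeros(shape),
            n_dep=np.full(shape, float(n_dep)),
            l_dry=np.zeros(shape),
            pulse_active=np.zeros(shape, dtype=bool),
            pulse_elapsed=np.zeros(shape),
            pulse_amplitude=np.ones(shape),
        )

    def copy(self) -> "SoilCellState":
        return SoilCellState(*(np.array(getattr(self, f)) for f in
                               ("n_natural", "n_fert", "n_dep", "l_dry",
                                "pulse_active", "pulse_elapsed", "pulse_amplitude")))


@dataclass
class EmissionField:
    """Hourly soil NOx flux grid with mass aggregation.

    flux in ng N m^-2 s^-1; ``cell_area`` in m^2 (scalar or (ny, nx) grid);
    ``component`` labels which nitrogen inputs were active for the run.
    """

    time: pd.DatetimeIndex
    flux: np.ndarray             # (nt, ny, nx)
    cell_area: np.ndarray        # m^2
    lat: np.ndarray
    lon: np.ndarray
    component: str = "total"

    def __post_init__(self):
        self.cell_area = np.broadcast_to(
            np.asarray(self.cell_area, dtype=float), self.flux.shape[1:]
        )

    def hourly_mass_tg(self) -> np.ndarray:
        """Mass emitted each hour, Tg N, summed over the grid."""
        per_cell = self.flux * self.cell_area * SECONDS_PER_HOUR / NG_PER_TG
        return per_cell.sum(axis=(1, 2))

    def monthly_totals(self) -> pd.Series:
        """Tg N per calendar month."""
        s = pd.Series(self.hourly_mass_tg(), index=self.time)
        return s.groupby(s.index.to_period("M")).sum()

    def total_mass_tg(self) -> float:
        return float(self.hourly_mass_tg().sum())

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "flux": (("time", "lat", "lon"), self.flux, {"units": "ng N m-2 s-1"}),
                "cell_area": (("lat", "lon"), np.asarray(self.cell_area), {"units": "m2"}),
            },
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            attrs={"component": self.component},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EmissionField":
        return cls(
            time=pd.DatetimeIndex(ds.time.values),
            flux=ds.flux.values,
            cell_area=ds.cell_area.values,
            lat=ds.lat.values,
            lon=ds.lon.values,
            component=ds.attrs.get("component", "total"),
        )


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

def temperature_response(T, params: BdsnpParams):
    """f(T) = exp(temp_coeff * T) with T clamped to [temp_min, temp_max] degC."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("soil temperature must be finite")
    Tc = np.clip(T, params.temp_min, params.temp_max)
    out = np.exp(params.temp_coeff * Tc)
    return out if out.ndim else float(out)


def moisture_response(theta, arid, params: BdsnpParams):
    """g(theta) = a * theta * exp(-b * theta^2), peaking (at 1) at theta_opt.

    ``arid`` may be a bool or a boolean array broadcastable against theta;
    it selects between the arid (theta_opt = 0.2) and non-arid (0.3)
    coefficient pairs.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta (water-filled pore space) must lie in [0, 1]")
    arid = np.asarray(arid, dtype=bool)
    a = np.where(arid, params.moisture_a(True), params.moisture_a(False))
    b = np.where(arid, params.moisture_b(True), params.moisture_b(False))
    out = a * theta * np.exp(-b * theta * theta)
    return out if out.ndim else float(out)


def pulse_amplitude_at_wetting(l_dry, params: BdsnpParams):
    """Pulse enhancement at the moment of wetting: 13.01 ln(l_dry) - 53.6.

    Defined as 0 (no pulse) for l_dry = 0; pulses only start when the
    bracket exceeds 1.
    """
    l = np.asarray(l_dry, dtype=float)
    with np.errstate(divide="ignore"):
        amp = params.pulse_log_coeff * np.log(l) - params.pulse_log_offset
    amp = np.where(l > 0, amp, -np.inf)
    return amp if amp.ndim else float(amp)


def update_dry_spell(state: SoilCellState, theta, dt: float,
                     params: BdsnpParams) -> SoilCellState:
    """Advance the dry-spell clock / pulse state machine by one step of dt hours.

    Below ``dry_theta_threshold`` the clock accumulates.  At or above it a
    wetting event is registered: a pulse starts if the amplitude bracket
    exceeds 1, and the clock resets.  Active pulses age by dt and deactivate
    once the decayed enhancement reaches 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = np.broadcast_to(np.asarray(theta, dtype=float), state.l_dry.shape)
    s = state.copy()
    dry = theta < params.dry_theta_threshold

    # age pulses that are already running
    s.pulse_elapsed = np.where(s.pulse_active, s.pulse_elapsed + dt, s.pulse_elapsed)
    decayed = s.pulse_amplitude * np.exp(-params.pulse_c * s.pulse_elapsed)
    expired = s.pulse_active & (decayed <= 1.0)
    s.pulse_active = s.pulse_active & ~expired

    # wetting: evaluate pulse initiation from the antecedent dry spell
    wet = ~dry
    amp = pulse_amplitude_at_wetting(s.l_dry, params)
    start = wet & ~s.pulse_active & (s.l_dry > 0) & (amp > 1.0)
    s.pulse_amplitude = np.where(start, amp, s.pulse_amplitude)
    s.pulse_elapsed = np.where(start, 0.0, s.pulse_elapsed)
    s.pulse_active = s.pulse_active | start

    s.l_dry = np.where(dry, s.l_dry + dt, 0.0)
    return s


def pulse_factor(state: SoilCellState, params: BdsnpParams):
    """Current pulse enhancement: max(1, amplitude * exp(-c t)) while active, else 1."""
    decayed = state.pulse_amplitude * np.exp(-params.pulse_c * state.pulse_elapsed)
    out = np.where(state.pulse_active, np.maximum(1.0, decayed), 1.0)
    return out if out.ndim else float(out)


def fertilizer_pool_step(state: SoilCellState, daily_application, dt: float,
                         params: BdsnpParams) -> SoilCellState:
    """First-order decay of the fertilizer pool plus the current application.

    ``daily_application`` is kg N ha^-1 day^-1; dt is in hours.  The pool
    approaches application_rate * tau at steady state.
    """
    app = np.asarray(daily_application, dtype=float)
    if np.any(app < 0):
        raise ValueError("fertilizer application must be >= 0")
    s = state.copy()
    tau_h = params.fert_decay_tau * 24.0
    s.n_fert = s.n_fert * np.exp(-dt / tau_h) + app * (dt / 24.0)
    return s


def available_nitrogen(state: SoilCellState):
    """N_avail: natural + fertilizer + deposition pools, kg N ha^-1."""
    return state.n_natural + state.n_fert + state.n_dep


def soil_nox_flux(state: SoilCellState, soil_temperature, theta, arid, biome_id,
                  params: BdsnpParams):
    """Instantaneous flux, ng N m^-2 s^-1, for the current state and forcing."""
    biome_id = np.asarray(biome_id)
    try:
        base = np.vectorize(params.emission_base.__getitem__, otypes=[float])(biome_id)
        crf = np.vectorize(params.canopy_reduction.get, otypes=[float])(biome_id, 0.0)
    except KeyError as e:
        raise KeyError(f"unknown biome id {e} in emission_base table") from e
    navail = available_nitrogen(state)
    f = temperature_response(soil_temperature, params)
    g = moisture_response(theta, arid, params)
    p = pulse_factor(state, params)
    return (base + params.emission_n_slope * navail) * f * g * p * (1.0 - crf)


# ---------------------------------------------------------------------------
# model driver
# ---------------------------------------------------------------------------

class BdsnpModel:
    """Soil NOx emission simulator over a gridded hourly forcing record.

    Parameters
    ----------
    forcing : MetForcing
    fertilizer : FertilizerSchedule or None
        Daily nitrogen application; None disables the fertilizer pool.
    dep_pool : float or (ny, nx) array
        Exogenous deposition nitrogen pool, kg N ha^-1, held constant.
    params : BdsnpParams
    cell_area : float or (ny, nx) array, m^2
    n_natural : float or array, kg N ha^-1, constant natural pool
    """

    def __init__(self, forcing: MetForcing, fertilizer: Optional[FertilizerSchedule],
                 params: Optional[BdsnpParams] = None, *, dep_pool=0.0,
                 cell_area=1.0e6, n_natural=0.5):
        self.forcing = forcing
        self.fertilizer = fertilizer
        self.params = (params or BdsnpParams()).validate()
        self.dep_pool = dep_pool
        self.cell_area = cell_area
        self.n_natural = n_natural
        if fertilizer is not None:
            f_days = set(fertilizer.days.normalize())
            m_days = set(forcing.time.normalize())
            if not m_days <= f_days:
                raise ValueError(
                    f"time-axis mismatch: forcing covers {len(m_days)} days, "
                    f"fertilizer schedule {len(f_days)}"
                )

    def run(self, *, include_fertilizer: bool = True,
            include_deposition: bool = True) -> EmissionField:
        """Advance every cell hourly and return the flux field.

        Component runs (fertilizer or deposition zeroed) use identical
        meteorology and pulse state so that differences isolate the pool.
        """
        fc = self.forcing
        nt = len(fc.time)
        shape = fc.grid_shape
        dt = float(np.round((fc.time[1] - fc.time[0]).total_seconds() / 3600.0)) if nt > 1 else 1.0
        dep = self.dep_pool if include_deposition else 0.0
        state = SoilCellState.zeros(shape, n_natural=self.n_natural, n_dep=dep)
        flux = np.empty((nt,) + shape)
        current_day = None
        todays_app = np.zeros(shape)
        for i, ts in enumerate(fc.time):
            day = ts.normalize()
            if day != current_day:
                current_day = day
                if self.fertilizer is not None and include_fertilizer:
                    todays_app = self.fertilizer.for_date(day)
                else:
                    todays_app = np.zeros(shape)
            state = fertilizer_pool_step(state, todays_app, dt, self.params)
            state = update_dry_spell(state, fc.wfps[i], dt, self.params)
            flux[i] = soil_nox_flux(state, fc.soil_temperature[i], fc.wfps[i],
                                    fc.arid_mask, fc.biome_id, self.params)
        parts = ["natural"]
        if include_fertilizer and self.fertilizer is not None:
            parts.append("fertilizer")
        if include_deposition:
            parts.append("deposition")
        component = "total" if len(parts) == 3 else "+".join(parts)
        return EmissionField(time=fc.time, flux=flux, cell_area=self.cell_area,
                             lat=fc.lat, lon=fc.lon, component=component)


def run_simulation(forcing: MetForcing, fertilizer: Optional[FertilizerSchedule],
                   params: Optional[BdsnpParams] = None, **kw) -> EmissionField:
    """Convenience wrapper: build a :class:`BdsnpModel` and run it."""
    run_kw = {k: kw.pop(k) for k in ("include_fertilizer", "include_deposition")
              if k in kw}
    return BdsnpModel(forcing, fertilizer, params, **kw).run(**run_kw)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def fertilizer_fraction(with_fert: EmissionField, without_fert: EmissionField):
    """Fraction of emissions attributable to fertilizer input.

    Returns ``(fraction_grid, regional_scalar)``: the per-cell fraction of the
    time-integrated flux, masked (NaN) where the with-fertilizer total is zero,
    and the emission-weighted regional fraction.
    """
    if with_fert.flux.shape != without_fert.flux.shape:
        raise ValueError("mismatched grids between component runs")
    tot_w = with_fert.flux.sum(axis=0)
    tot_wo = without_fert.flux.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot_w > 0, (tot_w - tot_wo) / tot_w, np.nan)
    weights = tot_w * with_fert.cell_area
    denom = weights.sum()
    regional = float(((tot_w - tot_wo) * with_fert.cell_area).sum() / denom) if denom > 0 else float("nan")
    return frac, regional


def scale_soil_emissions(field: EmissionField, factor: float) -> EmissionField:
    """Uniform multiplicative scaling of the flux field (totals scale exactly)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(field, flux=field.flux * float(factor))
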