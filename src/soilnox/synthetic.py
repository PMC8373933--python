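"""Synthetic inputs for the full pipeline: meteorology, fertilizer maps,
scenario ozone fields with a known emission-ozone response surface, and
station ozone series.

Everything is generated from a :class:`~soilnox.params.SyntheticConfig` and a
seed, deterministically — identical config + seed gives bit-identical output.
The scenario generator stores its ground-truth response parameters alongside
the fields so that recovery tests read the truth instead of re-deriving it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .bdsnp import FertilizerSchedule, MetForcing
from .params import ConfigError, SyntheticConfig
from .scenarios import ScenarioLabel

UGM3_PER_PPB = 48.00 / 22.414  # O3 at 273.15 K, 1 atm


# ---------------------------------------------------------------------------
# meteorology
# ---------------------------------------------------------------------------

def gen_met_forcing(cfg: SyntheticConfig) -> MetForcing:
    """Hourly soil temperature, bucket-model soil moisture, and arid/biome maps.

    Temperature is a diurnal sine (minimum near 05:00 local) with a small
    cell-specific offset so the record spans at least [0, 30] degC somewhere.
    Water-filled pore space follows a bucket model,
    ``theta(t+dt) = theta(t) * exp(-dt / tau_dry) + rain pulse``, with rain
    events drawn per cell per day.  Cell (0, 0) is scripted: it receives no
    rain until its dry spell exceeds ``cfg.dry_spell_target`` hours and is
    then wetted, guaranteeing one pulse-triggering event in every record long
    enough to hold it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    ny, nx = cfg.grid_shape
    nt = int(round(cfg.n_days * 24 / cfg.timestep))
    time = pd.date_range(cfg.start_date, periods=nt, freq=f"{cfg.timestep}h")

    hours = (time.hour + time.minute / 60.0).to_numpy()
    # minimum at 05:00, maximum at 17:00 local
    diurnal = np.sin(2 * np.pi * (hours - 11.0) / 24.0)
    cell_offset = rng.uniform(-2.0, 2.0, size=(ny, nx))
    cell_offset.flat[0] = 0.0
    temp = (cfg.temp_mean + cfg.temp_amplitude * diurnal)[:, None, None] + cell_offset

    # daily rain draws, then hourly bucket integration
    rain_day = rng.random(size=(cfg.n_days, ny, nx)) < cfg.rain_probability
    rain_hour_of_day = rng.integers(0, 24, size=(cfg.n_days, ny, nx))
    rain_amount = rng.uniform(0.3, 0.6, size=(cfg.n_days, ny, nx))

    # scripted dry spell + wetting for cell (0, 0)
    rain_day[:, 0, 0] = False
    wet_hour = cfg.dry_spell_target + 2
    if wet_hour < nt:
        d, h = divmod(wet_hour, 24)
        rain_day[d, 0, 0] = True
        rain_hour_of_day[d, 0, 0] = h
        rain_amount[d, 0, 0] = 0.6
        # allow ordinary rain again afterwards
        later = rng.random(size=(cfg.n_days, )) < cfg.rain_probability
        rain_day[d + 1:, 0, 0] = later[d + 1:]

    theta = np.empty((nt, ny, nx))
    theta0 = np.full((ny, nx), 0.25)
    theta0[0, 0] = 0.12  # start the scripted cell already dry
    decay = np.exp(-cfg.timestep / cfg.tau_dry)
    cur = theta0
    for i, ts in enumerate(time):
        cur = cur * decay
        day_idx = (ts.normalize() - time[0].normalize()).days
        hit = rain_day[day_idx] & (rain_hour_of_day[day_idx] == ts.hour)
        cur = np.clip(cur + np.where(hit, rain_amount[day_idx], 0.0), 0.0, 1.0)
        theta[i] = cur

    n_arid = int(round(cfg.arid_frac * ny * nx))
    arid = np.zeros(ny * nx, dtype=bool)
    arid[:n_arid] = True
    arid = arid.reshape(ny, nx)
    biome = np.where(arid, 1, 2).astype(int)  # 1: arid shrubland, 2: cropland

    lat = 34.0 + 0.25 * np.arange(ny)
    lon = 113.0 + 0.3125 * np.arange(nx)
    return MetForcing(time=time, soil_temperature=temp, wfps=theta,
                      arid_mask=arid, biome_id=biome, lat=lat, lon=lon)


# ---------------------------------------------------------------------------
# fertilizer
# ---------------------------------------------------------------------------

def gen_fertilizer_map(cfg: SyntheticConfig) -> FertilizerSchedule:
    """Annual fertilizer nitrogen spread uniformly over the growing season.

    Each fertilized cell receives ``cfg.fert_total`` kg N ha^-1 over the
    season (zero outside it); ``cfg.fert_unfertilized_frac`` of cells get
    nothing, to exercise the fertilizer-fraction separation downstream.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    ny, nx = cfg.grid_shape
    start = pd.Timestamp(cfg.start_date).normalize()
    days = pd.date_range(start, periods=cfg.n_days, freq="D")
    doy = days.dayofyear.to_numpy()
    gs0, gs1 = cfg.growing_season
    in_season = (doy >= gs0) & (doy <= gs1)
    season_len = gs1 - gs0 + 1

    n_unfert = int(round(cfg.fert_unfertilized_frac * ny * nx))
    unfert = np.zeros(ny * nx, dtype=bool)
    if n_unfert:
        unfert[rng.choice(ny * nx, size=n_unfert, replace=False)] = True
    unfert = unfert.reshape(ny, nx)

    daily_rate = cfg.fert_total / season_len  # kg N ha^-1 day^-1
    app = np.where(in_season[:, None, None] & ~unfert, daily_rate, 0.0)
    return FertilizerSchedule(days=days, application=app)


# ---------------------------------------------------------------------------
# scenario ozone fields
# ---------------------------------------------------------------------------

def diurnal_weight(hours) -> np.ndarray:
    """Half-sine daytime shape between 07:00 and 19:00 local, nocturnal floor 0.3."""
    h = np.asarray(hours, dtype=float)
    day = (h >= 7) & (h < 19)
    w = np.where(day, np.sin(np.pi * (h - 7.0) / 12.0), 0.0)
    return 0.3 + 0.7 * w


@dataclass
class OzoneScenarioSet:
    """Labeled hourly ozone / H2O2 / HNO3 fields keyed by emission scenario."""

    data: xr.Dataset           # dims (scenario, time, lat, lon); vars o3, h2o2, hno3 [ppb]
    ground_truth: dict         # generator response parameters + per-scenario emissions

    @property
    def labels(self) -> List[str]:
        return [str(s) for s in self.data.scenario.values]

    def field(self, label, var: str = "o3") -> xr.DataArray:
        label = str(label)
        if label not in self.labels:
            raise KeyError(f"unknown scenario {label!r}; valid labels: {self.labels}")
        return self.data[var].sel(scenario=label)

    def save(self, path) -> None:
        ds = self.data.copy()
        ds.attrs["ground_truth"] = json.dumps(self.ground_truth)
        ds.to_netcdf(path, engine="scipy")
        # sidecar with the generator truth, for tests and provenance
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)

    @classmethod
    def load(cls, path) -> "OzoneScenarioSet":
        ds = xr.open_dataset(path, engine="scipy").load()
        truth = json.loads(ds.attrs.get("ground_truth", "{}"))
        return cls(data=ds, ground_truth=truth)


def scenario_emissions(label: ScenarioLabel, rp) -> Dict[str, float]:
    """Ground-truth emission strengths implied by a scenario label."""
    return {
        "e_anthro": rp.e_anthro * label.anthro_fraction,
        "e_soil": rp.e_soil * label.soil_factor,
    }


def response_surface(e_anthro, e_soil, rp, hours):
    """The generator's ozone surface: d(t) * (B0 + alpha ln(1 + kappa E))."""
    e = np.asarray(e_anthro, dtype=float) + np.asarray(e_soil, dtype=float)
    level = rp.b0 + rp.alpha * np.log1p(rp.kappa * e)
    return diurnal_weight(hours) * level


def gen_scenario_ozone(cfg: SyntheticConfig,
                       scenarios: Sequence[ScenarioLabel]) -> OzoneScenarioSet:
    """Hourly scenario fields from a saturating emission-ozone response surface.

    Ozone is ``d(t) * (B0 + alpha ln(1 + kappa (E_anthro + E_soil)))`` plus
    clipped Gaussian noise; HNO3 rises with total NOx emission while H2O2 is
    held fixed, so the H2O2/HNO3 ratio falls as anthropogenic emissions grow.
    The required scenario labels BASE, NoSoil, NoAnthro and NoAnthroSoil must
    all be present.
    """
    cfg.validate()
    labels = [ScenarioLabel.parse(s) if isinstance(s, str) else s for s in scenarios]
    names = [str(l) for l in labels]
    required = {"BASE", "NoSoil", "NoAnthro", "NoAnthroSoil"}
    if not required <= set(names):
        raise ConfigError(
            f"scenario list must include {sorted(required)}; got {names}"
        )
    rp = cfg.response_params
    rng = np.random.default_rng(cfg.rng_seed + 2)
    ny, nx = cfg.grid_shape
    nt = cfg.n_days * 24
    time = pd.date_range(cfg.start_date, periods=nt, freq="h")
    hours = time.hour.to_numpy()

    # mild static spatial texture, shared by all scenarios (cancels in differences)
    spatial = 1.0 + 0.05 * np.sin(np.linspace(0, np.pi, ny))[:, None] \
                  * np.cos(np.linspace(0, np.pi, nx))[None, :]

    o3 = np.empty((len(labels), nt, ny, nx))
    h2o2 = np.empty_like(o3)
    hno3 = np.empty_like(o3)
    truth_scen = {}
    for k, lab in enumerate(labels):
        em = scenario_emissions(lab, rp)
        surf = response_surface(em["e_anthro"], em["e_soil"], rp, hours)
        field = surf[:, None, None] * spatial[None, :, :]
        if rp.noise_sd > 0:
            field = field + rng.normal(0.0, rp.noise_sd, size=field.shape)
        o3[k] = np.clip(field, 0.0, None)
        e_tot = em["e_anthro"] + em["e_soil"]
        h2o2[k] = rp.h2o2_level
        hno3[k] = rp.hno3_floor + rp.hno3_slope * e_tot
        truth_scen[str(lab)] = em

    lat = 34.0 + 0.25 * np.arange(ny)
    lon = 113.0 + 0.3125 * np.arange(nx)
    ds = xr.Dataset(
        {
            "o3": (("scenario", "time", "lat", "lon"), o3, {"units": "ppb"}),
            "h2o2": (("scenario", "time", "lat", "lon"), h2o2, {"units": "ppb"}),
            "hno3": (("scenario", "time", "lat", "lon"), hno3, {"units": "ppb"}),
        },
        coords={"scenario": names, "time": time, "lat": lat, "lon": lon},
    )
    truth = {
        "response_params": dataclasses.asdict(rp),
        "scenario_emissions": truth_scen,
        "spatial_pattern": "1 + 0.05 sin(pi y/(ny-1)) cos(pi x/(nx-1))",
    }
    return OzoneScenarioSet(data=ds, ground_truth=truth)


# ---------------------------------------------------------------------------
# station series
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStationData:
    """A station record in reporting units plus its ppb ground truth."""

    series: "pd.DataFrame"     # columns: station_id, timestamp, o3_ugm3
    truth_ppb: "pd.Series"     # indexed by timestamp, no gaps
    all_missing: bool = False


def gen_station_series(cfg: SyntheticConfig, *, constant_ppb: Optional[float] = None,
                       missing_frac: Optional[float] = None) -> SyntheticStationData:
    """Hourly station ozone in ug m^-3 (273.15 K, 1 atm) with injected gaps.

    The ppb truth follows the diurnal weight scaled to a realistic urban
    summer range plus noise; ``constant_ppb`` overrides it with a flat series
    (handy for conversion checks).  ``missing_frac`` of hours are set to NaN.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 3)
    nt = cfg.n_days * 24
    time = pd.date_range(cfg.start_date, periods=nt, freq="h")
    if constant_ppb is not None:
        ppb = np.full(nt, float(constant_ppb))
    else:
        base = 75.0 * diurnal_weight(time.hour.to_numpy())
        ppb = np.clip(base + rng.normal(0, 4.0, size=nt), 0.0, None)
    frac = cfg.station_missing_frac if missing_frac is None else missing_frac
    ugm3 = ppb * UGM3_PER_PPB
    miss = rng.random(nt) < frac
    ugm3 = np.where(miss, np.nan, ugm3)
    df = pd.DataFrame({"station_id": "S0001", "timestamp": time, "o3_ugm3": ugm3})
    return SyntheticStationData(
        series=df,
        truth_ppb=pd.Series(ppb, index=time, name="o3_ppb"),
        all_missing=bool(np.all(miss)),
    )
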