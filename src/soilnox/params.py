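"""Parameter containers for the soil NOx emission model and synthetic-data generators.

All parameter objects are plain dataclasses that round-trip through
``to_dict``/``from_dict`` (and hence YAML) losslessly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; message names the field."""


@dataclass
class BdsnpParams:
    """Parameters of the Berkeley-Dalhousie soil NOx parameterization (BDSNP).

    The hourly soil NO flux per grid cell is

        flux = [base(biome) + gamma * N_avail] * f(T) * g(theta) * P(l_dry) * (1 - CRF)

    with the temperature response ``f(T) = exp(temp_coeff * T)`` for soil
    temperature T clamped to [temp_min, temp_max] degC, the moisture response
    ``g(theta) = a * theta * exp(-b * theta**2)`` over water-filled pore space
    theta in [0, 1], and the wetting-pulse term
    ``P = max(1, [13.01 ln(l_dry) - 53.6] * exp(-c t))``.

    ``a`` and ``b`` are not free: ``b = 1/(2 theta_opt**2)`` places the maximum
    of g at ``theta_opt`` (0.2 for arid soils, 0.3 elsewhere) and ``a`` is set
    so that ``g(theta_opt) = 1``, making f*g a pure modulation of the
    emission-factor term.

    Notes
    -----
    The pulse decay rate ``pulse_c`` (h^-1) has no published numerical value;
    the default 0.068 h^-1 (about a 14.7 h e-folding) is a deliberate, exposed
    choice — override it if you have site-level pulse decay information.
    Nitrogen pools are in kg N ha^-1 and fluxes in ng N m^-2 s^-1.
    """

    temp_coeff: float = 0.103          # per degC
    temp_min: float = 0.0              # degC, lower clamp of f(T)
    temp_max: float = 30.0             # degC, upper clamp of f(T)
    theta_opt_arid: float = 0.2        # WFPS at which g peaks on arid soils
    theta_opt_other: float = 0.3       # WFPS at which g peaks elsewhere
    pulse_log_coeff: float = 13.01     # multiplies ln(l_dry) at pulse onset
    pulse_log_offset: float = 53.6     # subtracted at pulse onset
    pulse_c: float = 0.068             # h^-1, pulse decay rate (not fixed by published form)
    dry_theta_threshold: float = 0.15  # WFPS below which an hour counts as dry
    fert_decay_tau: float = 120.0      # days, e-folding of the fertilizer N pool
    emission_base: Dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.15, 2: 0.9}
    )                                  # ng N m^-2 s^-1 per biome id
    emission_n_slope: float = 0.05     # gamma, ng N m^-2 s^-1 per kg N ha^-1
    canopy_reduction: Dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.0, 2: 0.0}
    )                                  # fraction 0-1 per biome id

    # ---- derived moisture-response coefficients -------------------------
    def theta_opt(self, arid: bool) -> float:
        return self.theta_opt_arid if arid else self.theta_opt_other

    def moisture_b(self, arid: bool) -> float:
        """b such that d/dtheta [theta exp(-b theta^2)] = 0 at theta_opt."""
        t = self.theta_opt(arid)
        return 1.0 / (2.0 * t * t)

    def moisture_a(self, arid: bool) -> float:
        """a such that g(theta_opt) = 1."""
        t = self.theta_opt(arid)
        return math.exp(0.5) / t

    def validate(self) -> "BdsnpParams":
        if not 0 < self.theta_opt_arid < 1:
            raise ConfigError("theta_opt_arid must lie in (0, 1)")
        if not 0 < self.theta_opt_other < 1:
            raise ConfigError("theta_opt_other must lie in (0, 1)")
        if self.pulse_c <= 0:
            raise ConfigError("pulse_c must be positive")
        if not 0 <= self.dry_theta_threshold <= 1:
            raise ConfigError("dry_theta_threshold must lie in [0, 1]")
        if self.fert_decay_tau <= 0:
            raise ConfigError("fert_decay_tau must be positive")
        for b, crf in self.canopy_reduction.items():
            if not 0 <= crf <= 1:
                raise ConfigError(f"canopy_reduction[{b}] must lie in [0, 1]")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: biome tables keyed by int survive str round-trips
        d["emission_base"] = {int(k): float(v) for k, v in d["emission_base"].items()}
        d["canopy_reduction"] = {int(k): float(v) for k, v in d["canopy_reduction"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BdsnpParams":
        d = dict(d)
        for key in ("emission_base", "canopy_reduction"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d).validate()


@dataclass
class ResponseParams:
    """Ground-truth parameters of the synthetic emission-to-ozone surface.

    Daytime ozone is ``d(t) * (B0 + alpha * ln(1 + kappa * (E_anthro + E_soil)))``
    where d(t) is a diurnal weight (half-sine 07:00-19:00 local, nocturnal
    floor) — a saturating surface, so adding soil emissions suppresses the
    marginal ozone response to anthropogenic emissions, which is the behaviour
    the attribution stage must detect.
    """

    b0: float = 20.0          # ppb background
    alpha: float = 25.0       # ppb, curvature amplitude
    kappa: float = 1.2        # per unit emission, saturation scale
    e_anthro: float = 3.0     # anthropogenic emission strength at r = 0 (arbitrary units)
    e_soil: float = 1.0       # soil emission strength with soil on
    noise_sd: float = 0.0     # ppb additive Gaussian noise (clipped at 0 ppb)
    # H2O2/HNO3 generator: hno3 = hno3_slope * E_total + hno3_floor; h2o2 fixed.
    h2o2_level: float = 1.0
    hno3_slope: float = 1.1
    hno3_floor: float = 0.25


@dataclass
class SyntheticConfig:
    """Configuration of every synthetic-data generator.

    Identical config + seed gives bit-identical outputs across all generators.
    """

    grid_shape: tuple = (6, 8)          # (rows, cols) = (lat, lon)
    n_days: int = 30
    timestep: float = 1.0               # hours
    rng_seed: int = 0
    rain_probability: float = 0.12      # per cell per day
    dry_spell_target: int = 100         # hours; one engineered spell exceeds this
    growing_season: tuple = (91, 273)   # day-of-year start/end, inclusive
    fert_total: float = 60.0            # kg N ha^-1 per fertilized cell per year
    fert_unfertilized_frac: float = 0.3  # fraction of cells left unfertilized
    arid_frac: float = 0.25             # fraction of cells flagged arid
    tau_dry: float = 72.0               # h, bucket-model drying e-folding time
    start_date: str = "2017-07-01"
    utc_offset: int = 8                 # hours; timestamps are local time
    temp_mean: float = 17.0             # degC, diurnal mean
    temp_amplitude: float = 16.0        # degC, diurnal half-range
    dep_pool: float = 2.0               # kg N ha^-1, exogenous deposition pool
    station_missing_frac: float = 0.05
    response_params: ResponseParams = field(default_factory=ResponseParams)

    def validate(self) -> "SyntheticConfig":
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ConfigError("grid_shape dims must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        for name in ("rain_probability", "fert_unfertilized_frac", "arid_frac",
                     "station_missing_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.response_params.noise_sd < 0:
            raise ConfigError("response_params.noise_sd must be >= 0")
        if self.growing_season[1] < self.growing_season[0]:
            raise ConfigError("growing_season end before start")
        if self.fert_total < 0:
            raise ConfigError("fert_total must be >= 0")
        if self.tau_dry <= 0:
            raise ConfigError("tau_dry must be positive")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["growing_season"] = list(self.growing_season)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "growing_season" in d:
            d["growing_season"] = tuple(d["growing_season"])
        if isinstance(d.get("response_params"), dict):
            d["response_params"] = ResponseParams(**d["response_params"])
        return cls(**d).validate()
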