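import numpy as np
import pandas as pd
import pytest
import xarray as xr

from soilnox import SyntheticConfig, gen_fertilizer_map, gen_met_forcing, \
    gen_scenario_ozone
from soilnox.scenarios import reduction_ladder
from soilnox.synthetic import OzoneScenarioSet


@pytest.fixture(scope="session")
def cfg_small():
    return SyntheticConfig(grid_shape=(4, 5), n_days=8, rng_seed=42)


@pytest.fixture(scope="session")
def forcing_small(cfg_small):
    return gen_met_forcing(cfg_small)


@pytest.fixture(scope="session")
def fert_small(cfg_small):
    return gen_fertilizer_map(cfg_small)


@pytest.fixture(scope="session")
def ladder_cfg():
    return SyntheticConfig(grid_shape=(3, 4), n_days=10, rng_seed=7)


@pytest.fixture(scope="session")
def ladder_set(ladder_cfg):
    """Noise-free scenario set covering the reduction ladder with soil on and off."""
    labels = reduction_ladder("on") + reduction_ladder("off")
    return gen_scenario_ozone(ladder_cfg, labels)


def make_additive_set(n_days=3, ny=2, nx=2, b0=10.0, ca=5.0, cs=2.0):
    """Scenario set whose ozone response is exactly additive in the sources.

    O3 = d(t) * (b0 + ca * E_anthro + cs * E_soil); on such a surface the
    soil-anthropogenic interaction vanishes identically.
    """
    from soilnox.synthetic import diurnal_weight

    time = pd.date_range("2017-07-01", periods=n_days * 24, freq="h")
    d = diurnal_weight(time.hour.to_numpy())
    fields = {}
    for name, ea, es in [("BASE", 1.0, 1.0), ("NoSoil", 1.0, 0.0),
                         ("NoAnthro", 0.0, 1.0), ("NoAnthroSoil", 0.0, 0.0)]:
        fields[name] = (d * (b0 + ca * ea + cs * es))[:, None, None] \
            * np.ones((1, ny, nx))
    names = list(fields)
    o3 = np.stack([fields[n] for n in names])
    ds = xr.Dataset(
        {"o3": (("scenario", "time", "lat", "lon"), o3, {"units": "ppb"})},
        coords={"scenario": names, "time": time,
                "lat": np.arange(ny, dtype=float), "lon": np.arange(nx, dtype=float)},
    )
    return OzoneScenarioSet(data=ds, ground_truth={"form": "additive",
                                                   "b0": b0, "ca": ca, "cs": cs})
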