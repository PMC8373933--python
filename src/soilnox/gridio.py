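"""Shared I/O: CF-style NetCDF round-trips, station CSV, configs, manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Optional

import pandas as pd
import xarray as xr
import yaml

from .params import SyntheticConfig

ENGINE = "scipy"  # NetCDF3 classic


class SchemaError(ValueError):
    """A gridded file violates the expected CF-style layout."""


def save_gridded(path, ds: xr.Dataset) -> None:
    """Write a dataset as CF-style NetCDF; every data variable must carry units."""
    for name, var in ds.data_vars.items():
        if "units" not in var.attrs:
            raise SchemaError(f"variable {name!r} has no units attribute")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=ENGINE)


def load_gridded(path, require_dims=("time", "lat", "lon")) -> xr.Dataset:
    """Read a CF-style NetCDF file, checking dimensions and units attributes."""
    ds = xr.open_dataset(path, engine=ENGINE).load()
    for d in require_dims:
        if d not in ds.dims:
            raise SchemaError(f"{path}: missing required dimension {d!r}")
    for name, var in ds.data_vars.items():
        if "units" not in var.attrs:
            raise SchemaError(f"{path}: variable {name!r} has no units attribute")
    return ds


def save_station_csv(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def load_station_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        return SyntheticConfig.from_dict(yaml.safe_load(fh))


def dump_config(cfg: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: SyntheticConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, *, stage: str, seed: Optional[int],
                   cfg: Optional[SyntheticConfig] = None, outputs=()) -> dict:
    """Record what a pipeline stage produced and from which config/seed."""
    from . import __version__
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "outputs": [str(o) for o in outputs],
        "package_version": __version__,
        "python_version": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
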