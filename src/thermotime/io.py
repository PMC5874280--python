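"""Readers, writers and run configuration.

Schemas (all temperatures degC, timestamps ISO-8601, missing values empty
or "NA"):

* hourly CSV: ``datetime,temperature[,flag]``
* daily CSV: ``date,tmin,tmax``
* radiation CSV: ``date,radiation_obs,radiation_pot`` (MJ m-2 d-1)
* grids: NetCDF with dims (time, lat, lon), variables tmin/tmax/elevation

Validation is strict and reports the offending line/timestamp; round-trip
write-then-read is lossless for finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml

__all__ = [
    "read_hourly_csv",
    "write_hourly_csv",
    "read_daily_csv",
    "write_daily_csv",
    "read_radiation_csv",
    "daily_from_hourly",
    "read_grid_netcdf",
    "write_grid_netcdf",
    "RunConfig",
    "load_config",
]

PLAUSIBLE_RANGE = (-60.0, 50.0)


class SchemaError(ValueError):
    """CSV content violates the documented schema."""


def read_hourly_csv(path) -> pd.DataFrame:
    """Read an hourly series; enforces strictly increasing unique stamps."""
    df = pd.read_csv(path, na_values=["NA"])
    missing = {"datetime", "temperature"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        df["datetime"] = pd.to_datetime(df["datetime"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable datetime ({exc})") from exc
    dup = df["datetime"].duplicated()
    if dup.any():
        first = df.loc[dup.idxmax(), "datetime"]
        raise SchemaError(f"{path}: duplicated hour {first} (line {dup.idxmax() + 2})")
    if not df["datetime"].is_monotonic_increasing:
        pos = int(np.argmax(df["datetime"].diff().dt.total_seconds().fillna(1) <= 0))
        raise SchemaError(f"{path}: timestamps not increasing at line {pos + 2}")
    t = df["temperature"]
    out = t.notna() & ((t < PLAUSIBLE_RANGE[0]) | (t > PLAUSIBLE_RANGE[1]))
    if out.any():
        raise SchemaError(
            f"{path}: temperature outside plausible range at line {int(out.idxmax()) + 2}"
        )
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    return df[["datetime", "temperature", "flag"]]


def write_hourly_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["datetime"] = pd.to_datetime(out["datetime"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="NA")


def read_daily_csv(path, on_inverted: str = "reject") -> pd.DataFrame:
    """Read a daily Tn/Tx table.

    ``on_inverted`` controls rows with tmin > tmax: ``reject`` (error,
    default), ``swap`` or ``drop``.
    """
    df = pd.read_csv(path, na_values=["NA"])
    missing = {"date", "tmin", "tmax"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    with np.errstate(invalid="ignore"):
        bad = (df["tmin"] > df["tmax"]).to_numpy()
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad)]
        if on_inverted == "reject":
            raise SchemaError(f"{path}: tmin > tmax on line(s) {lines}")
        if on_inverted == "swap":
            lo = df.loc[bad, "tmax"].to_numpy()
            df.loc[bad, "tmax"] = df.loc[bad, "tmin"].to_numpy()
            df.loc[bad, "tmin"] = lo
        elif on_inverted == "drop":
            df = df[~bad].reset_index(drop=True)
        else:
            raise ValueError(f"unknown on_inverted policy {on_inverted!r}")
    return df[["date", "tmin", "tmax"]]


def write_daily_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="NA")


def read_radiation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    missing = {"date", "radiation_obs", "radiation_pot"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def daily_from_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Extract daily Tn/Tx from an hourly record (1..24 stamp convention)."""
    ts = pd.to_datetime(hourly["datetime"])
    day = (ts - pd.Timedelta(hours=1)).dt.normalize()
    g = pd.DataFrame({"date": day, "t": hourly["temperature"]}).groupby("date")["t"]
    return pd.DataFrame(
        {"date": g.min().index, "tmin": g.min().to_numpy(), "tmax": g.max().to_numpy()}
    )


def read_grid_netcdf(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy").load()
    ds.close()
    return ds


def write_grid_netcdf(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine="scipy")


@dataclass
class RunConfig:
    """Declarative run configuration; CLI flags override these fields."""

    base_temperature: float = 10.0
    thresholds: list = field(default_factory=lambda: [200.0, 800.0])
    seed: int = 0
    hour_grid: str = "1-24"
    radiation_ratio_threshold: float = 0.9
    transmissivity: float = 0.75
    n_calibration_years: int = 25
    f_corr: float | None = None
    elevation_cutoff: float = 1500.0
    params: list | None = None  # [a, b, c]; None -> builtin generic
    sites: list = field(default_factory=list)  # dicts: id/lat/lon/std_meridian/elev


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)
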