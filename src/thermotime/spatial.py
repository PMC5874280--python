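"""Gridded application: maps of the mean threshold-crossing DOY and its SD.

For every grid cell and year, the daily Tn/Tx fields are expanded to hourly
temperatures with the (generic) diurnal parameters -- sunrise and sunset
taken from the cell's own latitude -- degree-days are accumulated, the
optional empirical correction is applied, and the first DOY reaching the
prescribed thermal sum is recorded.  Across years this yields, per cell,
the mean date, its inter-annual standard deviation and the count of years
in which the threshold was reached at all.

Cells are processed independently (the computation is embarrassingly
parallel; chunking must not change results).  Cells above a configurable
elevation cutoff (default 1500 m a.s.l.) are flagged: the generic
parameterisation is not trustworthy in high-alpine settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .degreedays import CorrectionFactor, agdd_from_matrix
from .model import ModelParams, diurnal_matrix, hour_grid_values
from .solar import sunrise_hours

__all__ = ["map_threshold_dates", "cell_threshold_doys"]

DEFAULT_ELEVATION_CUTOFF = 1500.0


def cell_threshold_doys(
    params: ModelParams,
    tmin: np.ndarray,
    tmax: np.ndarray,
    doys: np.ndarray,
    latitude: float,
    base_temperature: float,
    threshold: float,
    f_corr: float = 1.0,
    hours: np.ndarray | None = None,
) -> float:
    """Threshold DOY for one cell-year (NaN when not reached).

    ``tmin``/``tmax``/``doys`` cover one calendar year in order.
    """
    if hours is None:
        hours = hour_grid_values("1-24")
    rise = sunrise_hours(latitude, doys)
    temps = diurnal_matrix(params, tmin, tmax, rise, 24.0 - rise, hours)
    cum, _ = agdd_from_matrix(temps, base_temperature)
    cum = cum * f_corr
    hit = np.flatnonzero(cum >= threshold)
    return float(doys[hit[0]]) if hit.size else np.nan


def map_threshold_dates(
    grid: xr.Dataset,
    params: ModelParams,
    base_temperature: float = 10.0,
    threshold: float = 800.0,
    correction: CorrectionFactor | None = None,
    elevation_cutoff: float = DEFAULT_ELEVATION_CUTOFF,
) -> xr.Dataset:
    """Mean DOY of a thermal-sum threshold and its inter-annual SD, per cell.

    Parameters
    ----------
    grid : Dataset
        ``tmin``/``tmax`` on (time, lat, lon) in degC and ``elevation`` on
        (lat, lon) in metres; time must cover whole calendar years.
    correction : CorrectionFactor, optional
        Multiplicative degree-day correction (None: no correction).

    Returns
    -------
    Dataset with ``mean_doy``, ``sd_doy`` (NaN where fewer than 1 resp. 2
    years reach the threshold), ``n_years_reached`` and the boolean
    ``high_altitude`` flag on (lat, lon).
    """
    f = correction.f_corr if correction is not None else 1.0
    lats = grid["lat"].to_numpy()
    lons = grid["lon"].to_numpy()
    times = pd.DatetimeIndex(grid["time"].to_numpy())
    years = np.unique(times.year)
    hours = hour_grid_values("1-24")

    tmin = grid["tmin"].transpose("time", "lat", "lon").to_numpy()
    tmax = grid["tmax"].transpose("time", "lat", "lon").to_numpy()

    doy_stack = np.full((len(years), lats.size, lons.size), np.nan)
    for yi, year in enumerate(years):
        sel = times.year == year
        doys = times.dayofyear.to_numpy()[sel]
        for i, lat in enumerate(lats):
            rise = sunrise_hours(lat, doys)
            sets = 24.0 - rise
            for j in range(lons.size):
                temps = diurnal_matrix(
                    params, tmin[sel, i, j], tmax[sel, i, j], rise, sets, hours
                )
                cum, _ = agdd_from_matrix(temps, base_temperature)
                hit = np.flatnonzero(cum * f >= threshold)
                if hit.size:
                    doy_stack[yi, i, j] = doys[hit[0]]

    n_reached = np.sum(np.isfinite(doy_stack), axis=0)
    denom = np.where(n_reached > 0, n_reached, 1)
    mean_doy = np.nansum(doy_stack, axis=0) / denom
    mean_doy[n_reached == 0] = np.nan
    dev2 = np.nansum((doy_stack - mean_doy[None, :, :]) ** 2, axis=0)
    sd_doy = np.sqrt(dev2 / np.where(n_reached > 1, n_reached - 1, 1))
    sd_doy[n_reached < 2] = np.nan

    elevation = grid["elevation"].to_numpy()
    return xr.Dataset(
        data_vars={
            "mean_doy": (("lat", "lon"), mean_doy),
            "sd_doy": (("lat", "lon"), sd_doy),
            "n_years_reached": (("lat", "lon"), n_reached.astype(np.int32)),
            "high_altitude": (("lat", "lon"), elevation > elevation_cutoff),
            "elevation": (("lat", "lon"), elevation),
        },
        coords={"lat": lats, "lon": lons},
        attrs={
            "threshold_degC_d": threshold,
            "base_temperature_degC": base_temperature,
            "f_corr": f,
            "params_a": params.a,
            "params_b": params.b,
            "params_c": params.c,
            "elevation_cutoff_m": elevation_cutoff,
            "nodata": "NaN",
            "coordinate_convention": "cell centres, north-up",
        },
    )
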