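"""Synthetic multi-year station and grid weather with known ground truth.

Every other module is exercised against data produced here, so the
generator is first-class, seeded code.  It emulates a mid-latitude
(Swiss-plateau-like) temperature climate:

* a seasonal sinusoid for the daily mean (default 9 degC mean, 9 degC
  amplitude, warmest in mid-July),
* a seasonally modulated diurnal range (default 8 +- 3 degC),
* AR(1) day-to-day anomalies on the daily minimum and maximum,
* hourly temperatures from the diurnal-curve model at a known parameter
  triple, plus i.i.d. Gaussian hourly noise,
* a Bernoulli fraction of overcast days whose diurnal cycle is flattened
  and (optionally) given an afternoon minimum -- emulating the real-data
  phenomenon that a sizeable share of days have their minimum after noon,
* observed/potential radiation ratios drawn above the clear-sky threshold
  on clear days and below it on overcast days.

These are test fixtures with controlled structure, not climate claims:
there are no fronts, no persistence beyond AR(1), no humidity coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .calibration import StationData
from .model import GENERIC_PARAMS, ModelParams, diurnal_matrix, hour_grid_values
from .solar import SiteGeometry, extraterrestrial_daily_radiation, sunrise_hours

__all__ = ["SyntheticConfig", "SyntheticStation", "generate_station", "generate_grid"]


def _default_sites() -> list[SiteGeometry]:
    return [SiteGeometry(latitude=47.0, longitude=7.5, standard_meridian=15.0,
                         elevation=450.0)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults emulate a Swiss-plateau station."""

    true_params: ModelParams = GENERIC_PARAMS
    sites: list = field(default_factory=_default_sites)
    years: int = 3
    start_year: int = 2001
    annual_mean: float = 9.0          # degC
    annual_amplitude: float = 9.0     # degC, peak-to-mean
    warmest_doy: float = 196.0        # phase of the seasonal cycle
    diurnal_range_mean: float = 8.0   # degC Tx - Tn
    diurnal_range_amplitude: float = 3.0
    ar1_coefficient: float = 0.7      # day-to-day anomaly persistence
    ar1_sigma: float = 2.0            # degC marginal SD of Tn/Tx anomalies
    hourly_noise_sigma: float = 0.5   # degC i.i.d. on each hourly value
    overcast_fraction: float = 0.3
    flattening_factor: float = 0.3    # overcast diurnal amplitude multiplier
    displace_overcast_tn: bool = True
    clear_ratio_range: tuple = (0.92, 1.0)    # observed/potential radiation
    overcast_ratio_range: tuple = (0.30, 0.85)
    transmissivity: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overcast_fraction <= 1.0:
            raise ValueError("overcast fraction must be in [0, 1]")
        if not 0.0 < self.flattening_factor <= 1.0:
            raise ValueError("flattening factor must be in (0, 1]")
        if self.ar1_sigma < 0 or self.hourly_noise_sigma < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class SyntheticStation:
    """Generated record plus the ground truth the tests check against."""

    station: StationData
    labels: pd.DataFrame       # date, overcast, displaced, radiation ratio
    true_params: ModelParams
    forcing_daily: pd.DataFrame  # the generating (true) Tn/Tx per day


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """AR(1) series with stationary marginal SD ``sigma``."""
    if sigma == 0:
        return np.zeros(n)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + shocks[i - 1]
    return e


def _daily_forcing(config: SyntheticConfig, rng: np.random.Generator,
                   dates: pd.DatetimeIndex):
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.annual_mean + config.annual_amplitude * np.cos(
        2.0 * np.pi * (doy - config.warmest_doy) / 365.25
    )
    half_range = 0.5 * (
        config.diurnal_range_mean
        + config.diurnal_range_amplitude
        * np.cos(2.0 * np.pi * (doy - config.warmest_doy) / 365.25)
    )
    tn = seasonal - half_range + _ar1(rng, len(dates), config.ar1_coefficient,
                                      config.ar1_sigma)
    tx = seasonal + half_range + _ar1(rng, len(dates), config.ar1_coefficient,
                                      config.ar1_sigma)
    tx = np.maximum(tx, tn + 0.5)  # keep a physical Tn < Tx on every day
    return tn, tx


def generate_station(config: SyntheticConfig, site_index: int = 0) -> SyntheticStation:
    """Generate one station's multi-year "observed" record.

    Returns hourly temperatures (1..24 TST grid), the daily forcing series
    (clear days report the generating Tn/Tx; overcast days report the
    extrema of their own distorted hourly curve), daily observed and
    potential radiation, and per-day ground-truth labels.

    Fully deterministic given (config.seed, site_index).
    """
    geometry = config.sites[site_index]
    rng = np.random.default_rng([config.seed, site_index])

    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.years - 1}-12-31",
        freq="D",
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    tn, tx = _daily_forcing(config, rng, dates)

    rise = sunrise_hours(geometry.latitude, doy)
    sets = 24.0 - rise
    hours = hour_grid_values("1-24")
    clean = diurnal_matrix(config.true_params, tn, tx, rise, sets, hours)

    overcast = rng.random(n) < config.overcast_fraction
    displaced = overcast & config.displace_overcast_tn

    hourly = clean.copy()
    if overcast.any():
        mid = 0.5 * (tn + tx)
        hourly[overcast] = (
            mid[overcast, None]
            + (clean[overcast] - mid[overcast, None]) * config.flattening_factor
        )
    if displaced.any():
        # a tent-shaped cold intrusion centred mid-afternoon pushes the
        # day's minimum past noon, emulating frontal-passage days
        amp = (tx - tn) * config.flattening_factor
        tent = np.clip(1.0 - np.abs(hours[None, :] - 15.0) / 9.0, 0.0, None)
        hourly[displaced] = hourly[displaced] - 1.5 * amp[displaced, None] * tent
    if config.hourly_noise_sigma > 0:
        hourly = hourly + rng.normal(0.0, config.hourly_noise_sigma, size=hourly.shape)

    # reported daily series: the generating forcing on clear days, the
    # distorted curve's own extrema on overcast days (as a real archive,
    # which extracts Tn/Tx from hourly data, would show)
    tn_rep = tn.copy()
    tx_rep = tx.copy()
    tn_rep[overcast] = hourly[overcast].min(axis=1)
    tx_rep[overcast] = hourly[overcast].max(axis=1)
    with np.errstate(invalid="ignore"):
        bad = tn_rep > tx_rep
    tn_rep[bad], tx_rep[bad] = tx_rep[bad], tn_rep[bad]

    ratio = np.where(
        overcast,
        rng.uniform(*config.overcast_ratio_range, size=n),
        rng.uniform(*config.clear_ratio_range, size=n),
    )
    pot = np.array(
        [
            config.transmissivity * extraterrestrial_daily_radiation(geometry, int(d))
            for d in doy
        ]
    )

    stamp = (
        dates.to_numpy()[:, None] + (hours * 3.6e12).astype("timedelta64[ns]")[None, :]
    )
    hourly_df = pd.DataFrame(
        {"datetime": stamp.ravel(), "temperature": hourly.ravel()}
    )
    daily_df = pd.DataFrame({"date": dates, "tmin": tn_rep, "tmax": tx_rep})
    radiation_df = pd.DataFrame(
        {"date": dates, "radiation_obs": ratio * pot, "radiation_pot": pot}
    )
    labels = pd.DataFrame(
        {
            "date": dates,
            "overcast": overcast,
            "displaced": displaced,
            "radiation_ratio": ratio,
        }
    )
    station = StationData(
        station_id=f"SYN{site_index:02d}",
        geometry=geometry,
        hourly=hourly_df,
        daily=daily_df,
        radiation=radiation_df,
    )
    return SyntheticStation(
        station=station,
        labels=labels,
        true_params=config.true_params,
        forcing_daily=pd.DataFrame({"date": dates, "tmin": tn, "tmax": tx}),
    )


def generate_grid(
    config: SyntheticConfig,
    extent: tuple = (46.0, 47.0, 6.5, 8.0),
    resolution: float = 0.05,
    lapse_rate: float = -0.65,
    elevation: np.ndarray | None = None,
    reference_elevation: float = 450.0,
) -> xr.Dataset:
    """Gridded daily Tn/Tx: one station-style series shifted by elevation.

    Parameters
    ----------
    extent : (lat_min, lat_max, lon_min, lon_max) in degrees.
    resolution : cell size in degrees (cell-centre coordinates).
    lapse_rate : degC per 100 m (negative: cooler aloft).
    elevation : optional (n_lat, n_lon) array, metres; by default a smooth
        synthetic relief rising with latitude (300..1300 m) with a gentle
        longitudinal undulation.

    Returns an xarray Dataset with ``tmin``/``tmax`` on (time, lat, lon)
    and ``elevation`` on (lat, lon).
    """
    lat_min, lat_max, lon_min, lon_max = extent
    lats = np.arange(lat_min + resolution / 2, lat_max, resolution)
    lons = np.arange(lon_min + resolution / 2, lon_max, resolution)
    if lats.size == 0 or lons.size == 0:
        raise ValueError("empty extent")

    if elevation is None:
        rel_lat = (lats - lat_min) / max(lat_max - lat_min, 1e-9)
        elevation = (
            300.0
            + 1000.0 * rel_lat[:, None]
            + 50.0 * np.sin(2.0 * np.pi * (lons[None, :] - lon_min))
        )
    elevation = np.asarray(elevation, dtype=float)
    if elevation.shape != (lats.size, lons.size):
        raise ValueError("elevation shape does not match the grid")

    rng = np.random.default_rng([config.seed, 9999])
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.years - 1}-12-31",
        freq="D",
    )
    tn0, tx0 = _daily_forcing(config, rng, dates)

    shift = lapse_rate / 100.0 * (elevation - reference_elevation)
    tmin = tn0[:, None, None] + shift[None, :, :]
    tmax = tx0[:, None, None] + shift[None, :, :]

    return xr.Dataset(
        data_vars={
            "tmin": (("time", "lat", "lon"), tmin),
            "tmax": (("time", "lat", "lon"), tmax),
            "elevation": (("lat", "lon"), elevation),
        },
        coords={"time": dates, "lat": lats, "lon": lons},
        attrs={
            "title": "synthetic gridded daily Tn/Tx",
            "lapse_rate_degC_per_100m": lapse_rate,
            "reference_elevation_m": reference_elevation,
        },
    )
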