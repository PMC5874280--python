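"""Clear-sky day selection and parameter estimation.

The diurnal curve is only expected to hold on days with a regular radiative
regime, so calibration is restricted to "clear-sky" days: the daily minimum
must occur before solar noon and the observed/potential global radiation
ratio must exceed a threshold (default 0.9).  A seeded random subset of
years (default 25) supplies the candidate days.

Fitting maximises the modified index of agreement between observed hourly
temperatures and the reconstruction, pooled over all selected days'
concatenated hours, with a Nelder-Mead simplex on (a, b, c).  A "generic"
(pooled multi-site) fit is the same optimisation on the concatenation of
several stations' calibration sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import metrics as _metrics
from .model import ModelParams, SITE_MEAN_PARAMS, diurnal_matrix, hour_grid_values
from .solar import SiteGeometry, sunrise_hours

__all__ = [
    "ClearSkyCriteria",
    "StationData",
    "CalibrationSet",
    "CalibrationResult",
    "is_clear_sky_day",
    "build_calibration_set",
    "fit_parameters",
    "fit_generic",
    "evaluate_model",
]


@dataclass(frozen=True)
class ClearSkyCriteria:
    """Rules deciding whether a day enters the calibration set."""

    radiation_ratio_threshold: float = 0.9
    require_tn_before_noon: bool = True
    transmissivity: float = 0.75
    min_hour_smoothing: int = 7  # odd window (hours) for locating the minimum

    def __post_init__(self) -> None:
        if not 0.0 < self.radiation_ratio_threshold <= 1.0:
            raise ValueError("radiation ratio threshold must be in (0, 1]")
        if self.min_hour_smoothing < 1 or self.min_hour_smoothing % 2 == 0:
            raise ValueError("min_hour_smoothing must be a positive odd integer")


def _minimum_hour(temps: np.ndarray, hours: np.ndarray, window: int = 7) -> np.ndarray:
    """Clock hour (in [0, 24)) of each day's temperature minimum.

    ``temps`` is (n_days, n_hours).  The minimum is located on a centred
    moving average (window shrinking at the day edges) so that measurement
    noise on nearly equal night-time readings does not flip the
    morning/afternoon verdict.  The window (default +-3 h) is much shorter
    than the half-day scale of that verdict and cannot displace a genuine
    afternoon minimum across noon; on noise-free curves the smoothed and
    raw minima agree because the branches are monotone around the minimum.
    """
    t = np.asarray(temps, dtype=float)
    n_h = t.shape[1]
    k = window // 2
    sm = np.empty_like(t)
    for j in range(n_h):
        sm[:, j] = t[:, max(0, j - k): min(n_h, j + k + 1)].mean(axis=1)
    return hours[np.argmin(sm, axis=1)] % 24.0


@dataclass
class StationData:
    """One station's observed record: hourly + daily + radiation + location.

    ``hourly``: columns datetime, temperature (TST-hourly, 1..24 grid:
    the 00:00 stamp closes the previous day).
    ``daily``: columns date, tmin, tmax (contiguous calendar days).
    ``radiation``: columns date, radiation_obs, radiation_pot (MJ m-2 d-1);
    optional -- without it the radiation criterion is skipped.
    """

    station_id: str
    geometry: SiteGeometry
    hourly: pd.DataFrame
    daily: pd.DataFrame
    radiation: pd.DataFrame | None = None


def is_clear_sky_day(
    temperatures,
    hours_tst,
    radiation_obs: float,
    radiation_pot: float,
    criteria: ClearSkyCriteria = ClearSkyCriteria(),
) -> bool | None:
    """Classify one day.  Returns None (not False) for incomplete days.

    ``temperatures``/``hours_tst`` are that day's hourly values and their
    decimal TST hours.  The minimum-before-noon test uses the clock hour of
    the coldest record, read on [0, 24) -- the terminal midnight stamp of a
    1..24 sampling grid reads as hour 0, which is before noon; radiation
    enters as the observed/potential ratio.
    """
    t = np.asarray(temperatures, dtype=float)
    h = np.asarray(hours_tst, dtype=float)
    if t.size < 24 or np.isnan(t).any():
        return None
    if radiation_pot <= 0:
        raise ValueError("potential radiation must be positive")
    if criteria.require_tn_before_noon:
        order = np.argsort(h)
        if _minimum_hour(t[order][None, :], h[order],
                         criteria.min_hour_smoothing)[0] >= 12.0:
            return False
    return bool(radiation_obs / radiation_pot > criteria.radiation_ratio_threshold)


def _hourly_matrix(hourly: pd.DataFrame, dates: pd.Series, hours: np.ndarray):
    """Align an hourly record onto a (n_days, n_hours) matrix.

    With a 1..24 grid the end-of-interval convention applies (the stamp at
    ``date + h`` belongs to row ``date``, so 00:00 closes the previous
    day); a grid starting at 0 uses plain calendar-day attribution.
    """
    ts = pd.to_datetime(hourly["datetime"])
    shift = pd.Timedelta(hours=1 if hours.min() > 0 else 0)
    day = (ts - shift).dt.normalize()
    hour_of_day = ((ts - day).dt.total_seconds() / 3600.0).to_numpy()
    day_pos = pd.Series(np.arange(len(dates)), index=pd.DatetimeIndex(dates))
    rows = day_pos.reindex(day).to_numpy()
    cols = np.searchsorted(hours, hour_of_day)
    ok = (
        ~np.isnan(rows)
        & (cols < len(hours))
        & np.isclose(hours[np.minimum(cols, len(hours) - 1)], hour_of_day)
    )
    mat = np.full((len(dates), len(hours)), np.nan)
    mat[rows[ok].astype(int), cols[ok]] = hourly["temperature"].to_numpy(float)[ok]
    return mat


@dataclass
class CalibrationSet:
    """Pre-assembled arrays for one station's calibration days."""

    station_id: str
    tn: np.ndarray
    tx: np.ndarray
    sunrise: np.ndarray
    sunset: np.ndarray
    observed: np.ndarray  # (n_days, n_hours), NaN where missing
    clear_idx: np.ndarray  # indices into the daily arrays
    hours: np.ndarray
    n_years: int

    @property
    def n_days(self) -> int:
        return int(len(self.clear_idx))


def build_calibration_set(
    station: StationData,
    n_years: int = 25,
    criteria: ClearSkyCriteria = ClearSkyCriteria(),
    seed: int | None = None,
    hour_grid: str = "1-24",
) -> CalibrationSet:
    """Sample calibration years and collect their clear-sky days.

    Years are drawn uniformly without replacement with the given seed; if
    fewer than ``n_years`` are available all are used (with a warning).
    """
    daily = station.daily.reset_index(drop=True)
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    hours = hour_grid_values(hour_grid)
    obs = _hourly_matrix(station.hourly, dates, hours)

    years = np.sort(dates.dt.year.unique())
    if len(years) < n_years:
        warnings.warn(
            f"only {len(years)} years available; using all (requested {n_years})"
        )
        chosen = years
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(years, size=n_years, replace=False))
    in_years = dates.dt.year.isin(chosen).to_numpy()

    rad_ratio = None
    if station.radiation is not None:
        rad = station.radiation.copy()
        rad["date"] = pd.to_datetime(rad["date"]).dt.normalize()
        rad = rad.set_index("date").reindex(dates)
        rad_ratio = (rad["radiation_obs"] / rad["radiation_pot"]).to_numpy(float)

    complete = ~np.isnan(obs).any(axis=1)
    clear = np.zeros(len(daily), dtype=bool)
    clear[complete] = True
    if criteria.require_tn_before_noon:
        min_hour = _minimum_hour(np.where(complete[:, None], obs, 0.0), hours,
                                 criteria.min_hour_smoothing)
        clear &= min_hour < 12.0
    if rad_ratio is not None:
        with np.errstate(invalid="ignore"):
            clear &= rad_ratio > criteria.radiation_ratio_threshold

    clear_idx = np.flatnonzero(clear & in_years)

    doy = dates.dt.dayofyear.to_numpy()
    rise = sunrise_hours(station.geometry.latitude, doy)
    return CalibrationSet(
        station_id=station.station_id,
        tn=daily["tmin"].to_numpy(float),
        tx=daily["tmax"].to_numpy(float),
        sunrise=rise,
        sunset=24.0 - rise,
        observed=obs,
        clear_idx=clear_idx,
        hours=hours,
        n_years=int(len(chosen)),
    )


@dataclass
class CalibrationResult:
    params: ModelParams
    objective: float
    n_days: int
    n_years: int
    sites: list = field(default_factory=list)
    converged: bool = True
    start: ModelParams = SITE_MEAN_PARAMS
    n_iterations: int = 0
    realistic: bool = True

    def to_dict(self) -> dict:
        return {
            "a": self.params.a,
            "b": self.params.b,
            "c": self.params.c,
            "objective_mia": self.objective,
            "n_days": self.n_days,
            "n_years": self.n_years,
            "sites": self.sites,
            "converged": self.converged,
            "realistic": self.realistic,
            "start": [self.start.a, self.start.b, self.start.c],
            "n_iterations": self.n_iterations,
        }


_PENALTY = 10.0


def _pooled_objective(x, sets, per_day, objective_fn):
    a, b, c = x
    if b <= 0:
        return _PENALTY
    try:
        params = ModelParams(a=a, b=b, c=c)
    except ValueError:
        return _PENALTY
    obs_all, sim_all, scores = [], [], []
    for s in sets:
        try:
            sim = diurnal_matrix(params, s.tn, s.tx, s.sunrise, s.sunset, s.hours)
        except ValueError:
            return _PENALTY
        sim = sim[s.clear_idx]
        obs = s.observed[s.clear_idx]
        if per_day:
            for i in range(obs.shape[0]):
                mask = np.isfinite(obs[i])
                if mask.sum() >= 2 and np.ptp(obs[i][mask]) > 0:
                    scores.append(objective_fn(obs[i][mask], sim[i][mask]))
        else:
            obs_all.append(obs.ravel())
            sim_all.append(sim.ravel())
    if per_day:
        return 1.0 - float(np.mean(scores))
    obs_cat = np.concatenate(obs_all)
    sim_cat = np.concatenate(sim_all)
    mask = np.isfinite(obs_cat) & np.isfinite(sim_cat)
    return 1.0 - objective_fn(obs_cat[mask], sim_cat[mask])


def fit_parameters(
    calibration: CalibrationSet | list,
    start: ModelParams = SITE_MEAN_PARAMS,
    objective: str = "mia",
    per_day: bool = False,
    maxiter: int = 2000,
    xatol: float = 1e-6,
    fatol: float = 1e-9,
) -> CalibrationResult:
    """Nelder-Mead fit of (a, b, c) maximising the chosen agreement metric.

    The objective is the metric over the concatenated hours of every
    clear-sky day (``per_day=True`` averages a per-day metric instead).
    Non-convergence returns the best simplex point, flagged.
    """
    sets = calibration if isinstance(calibration, list) else [calibration]
    n_days = sum(s.n_days for s in sets)
    if n_days < 10:
        raise ValueError(f"need at least 10 calibration days, have {n_days}")
    objective_fn = getattr(_metrics, objective)
    res = minimize(
        _pooled_objective,
        start.as_array(),
        args=(sets, per_day, objective_fn),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
    )
    params = ModelParams(a=float(res.x[0]), b=float(res.x[1]), c=float(res.x[2]))
    result = CalibrationResult(
        params=params,
        objective=float(1.0 - res.fun),
        n_days=n_days,
        n_years=max(s.n_years for s in sets),
        sites=[s.station_id for s in sets],
        converged=bool(res.success),
        start=start,
        n_iterations=int(res.nit),
        realistic=params.is_realistic(),
    )
    if not result.realistic:
        warnings.warn(
            f"calibrated parameters {params} outside realistic bounds; "
            "flagged, not clipped"
        )
    return result


def fit_generic(calibration_sets: list, **kwargs) -> CalibrationResult:
    """Single pooled fit over several stations (the 'generic' model)."""
    if not calibration_sets:
        raise ValueError("need at least one station")
    return fit_parameters(list(calibration_sets), **kwargs)


_SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def evaluate_model(
    params: ModelParams,
    station: StationData,
    stratifier: str = "all",
    hour_grid: str = "1-24",
) -> pd.DataFrame:
    """Performance table (ME/MAE/RMSD/MIA/R2/NSE) for one station.

    ``stratifier``: ``"all"`` (one row), ``"by-hour"`` (one row per clock
    hour) or ``"by-season"`` (meteorological DJF/MAM/JJA/SON).  Empty
    strata are omitted with a warning.
    """
    daily = station.daily.reset_index(drop=True)
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    hours = hour_grid_values(hour_grid)
    obs = _hourly_matrix(station.hourly, dates, hours)
    doy = dates.dt.dayofyear.to_numpy()
    rise = sunrise_hours(station.geometry.latitude, doy)
    sim = diurnal_matrix(params, daily["tmin"].to_numpy(float),
                         daily["tmax"].to_numpy(float), rise, 24.0 - rise, hours)

    def strata():
        if stratifier == "all":
            yield "all", np.ones_like(obs, dtype=bool)
        elif stratifier == "by-hour":
            for j, h in enumerate(hours):
                m = np.zeros_like(obs, dtype=bool)
                m[:, j] = True
                yield f"{int(h) % 24:02d}:00", m
        elif stratifier == "by-season":
            month = dates.dt.month.map(_SEASONS).to_numpy()
            for season in ("DJF", "MAM", "JJA", "SON"):
                m = np.zeros_like(obs, dtype=bool)
                m[month == season, :] = True
                yield season, m
        else:
            raise ValueError(f"unknown stratifier {stratifier!r}")

    rows = []
    for name, m in strata():
        mask = m & np.isfinite(obs) & np.isfinite(sim)
        if mask.sum() < 2:
            warnings.warn(f"stratum {name} empty; omitted")
            continue
        rows.append({"stratum": name, **_metrics.compute_all(obs[mask], sim[mask])})
    return pd.DataFrame(rows)
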