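"""Three-branch diurnal temperature model.

Hourly temperature on day ``i`` is reconstructed from the daily minimum
``Tn_i``, the daily maximum ``Tx_i`` and the sunrise/sunset hours
``h_R``/``h_S`` (decimal true solar time) as a piecewise curve:

* before ``h_R,i + c`` -- exponential relaxation from yesterday's sunset
  temperature ``T_S,i-1`` towards today's minimum,
* between ``h_R,i + c`` and ``h_S,i`` -- a sine arc forced through ``Tn_i``
  (at ``h_R,i + c``) and ``Tx_i`` (at ``(h_R,i + h_S,i)/2 + a``),
* after ``h_S,i`` -- exponential relaxation from today's sunset temperature
  towards tomorrow's minimum ``Tn_i+1``.

The three parameters are ``a`` (lag of the maximum after solar noon, hours),
``b`` (night-time decay coefficient, dimensionless) and ``c`` (lag of the
minimum after sunrise, hours).

The night branches use the force-through form

    T(t) = Tn + (T_S - Tn) * [exp(-b t / n) - (t / n) exp(-b)]

with ``t`` the hours since the relevant sunset and ``n`` the corrected night
length (sunset to next day's ``h_R + c``).  The bracket vanishes at
``t = n``, so the curve passes exactly through ``Tn`` where the morning
night branch hands over to the sine arc, and the construction makes the
curve continuous across midnight.  A "literal" variant in which the additive
correction term is not scaled by ``(T_S - Tn)`` is kept for comparison
(``night_form="literal"``); it does not pass through ``Tn`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import SiteGeometry, SolarTimes, sunrise_hours

__all__ = [
    "ModelParams",
    "DayForcing",
    "GENERIC_PARAMS",
    "SITE_MEAN_PARAMS",
    "sunset_temperature",
    "hourly_temperature",
    "diurnal_matrix",
    "simulate_series",
    "hour_grid_values",
]


@dataclass(frozen=True)
class ModelParams:
    """Diurnal-curve parameters (a: hours, b: dimensionless, c: hours)."""

    a: float
    b: float
    c: float

    # sanity bounds; generous, configurable by constructing with check=False
    A_BOUNDS = (-2.0, 6.0)
    C_BOUNDS = (-2.0, 4.0)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"night decay coefficient b must be > 0, got {self.b}")

    def is_realistic(self) -> bool:
        """True when all parameters lie inside the sanity bounds.

        Calibrations can legitimately land outside (high-alpine sites
        produce a > 5.5); such optima are flagged, never clipped.
        """
        return (
            self.A_BOUNDS[0] < self.a < self.A_BOUNDS[1]
            and self.C_BOUNDS[0] < self.c < self.C_BOUNDS[1]
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


#: Pooled multi-site ("generic") parameter triple.
GENERIC_PARAMS = ModelParams(a=2.71, b=3.14, c=0.75)

#: Mean of site-specific calibrations; the default optimiser start.
SITE_MEAN_PARAMS = ModelParams(a=2.79, b=3.16, c=0.79)


@dataclass(frozen=True)
class DayForcing:
    """Everything the piecewise curve needs for one day.

    Neighbour-day context: yesterday's sunset temperature and sunset hour
    (for the pre-sunrise branch), tomorrow's minimum and sunrise hour (for
    the post-sunset branch).
    """

    t_n: float
    t_x: float
    t_n_next: float
    t_s_prev: float
    sunrise: float
    sunset: float
    sunset_prev: float
    sunrise_next: float

    def __post_init__(self) -> None:
        if self.t_n > self.t_x:
            raise ValueError(f"t_n ({self.t_n}) exceeds t_x ({self.t_x})")
        for name in ("sunrise", "sunset", "sunset_prev", "sunrise_next"):
            h = getattr(self, name)
            if not 0.0 <= h <= 24.0:
                raise ValueError(f"{name}={h} outside [0, 24]")


def _day_branch(params: ModelParams, t_n, t_x, h_r, h_s, h):
    """Sine arc between ``h_r + c`` and ``h_s`` (inclusive)."""
    denom = h_s - h_r + 2.0 * params.a - 2.0 * params.c
    return t_n + (t_x - t_n) * np.sin(np.pi * (h - h_r - params.c) / denom)


def _night_branch(params: ModelParams, t_n, t_s, t_since_sunset, night_length, form):
    tau = t_since_sunset / night_length
    if form == "forced":
        return t_n + (t_s - t_n) * (np.exp(-params.b * tau) - tau * np.exp(-params.b))
    if form == "literal":
        return t_n + (t_s - t_n) * np.exp(-params.b * tau) - tau * np.exp(-params.b)
    raise ValueError(f"unknown night_form {form!r}")


def sunset_temperature(
    params: ModelParams, t_n: float, t_x: float, times: SolarTimes
) -> float:
    """Temperature at sunset: the day branch evaluated at ``h_S``."""
    if t_n > t_x:
        raise ValueError("t_n exceeds t_x")
    if times.sunset <= times.sunrise + params.c:
        raise ValueError("degenerate daylength: sunset before sunrise + c")
    return float(
        _day_branch(params, t_n, t_x, times.sunrise, times.sunset, times.sunset)
    )


def hourly_temperature(
    params: ModelParams, forcing: DayForcing, h: float, night_form: str = "forced"
) -> float:
    """Evaluate the piecewise curve at decimal TST hour ``h`` of one day.

    The day branch owns both of its boundaries (``h = h_R + c`` and
    ``h = h_S``); the branches agree there, so the assignment is cosmetic.
    """
    if not 0.0 <= h <= 24.0:
        raise ValueError(f"h={h} outside [0, 24]")
    if h < forcing.sunrise + params.c:
        n1 = forcing.sunrise - forcing.sunset_prev + params.c + 24.0
        if n1 <= 0:
            raise ValueError("non-positive pre-sunrise night length")
        t = h - forcing.sunset_prev + 24.0
        return float(
            _night_branch(params, forcing.t_n, forcing.t_s_prev, t, n1, night_form)
        )
    if h <= forcing.sunset:
        return float(
            _day_branch(
                params, forcing.t_n, forcing.t_x, forcing.sunrise, forcing.sunset, h
            )
        )
    n2 = forcing.sunrise_next - forcing.sunset + params.c + 24.0
    if n2 <= 0:
        raise ValueError("non-positive post-sunset night length")
    t_s = sunset_temperature(
        params,
        forcing.t_n,
        forcing.t_x,
        SolarTimes(forcing.sunrise, forcing.sunset, 1),
    )
    return float(
        _night_branch(params, forcing.t_n_next, t_s, h - forcing.sunset, n2, night_form)
    )


def diurnal_matrix(
    params: ModelParams,
    t_n: np.ndarray,
    t_x: np.ndarray,
    sunrise: np.ndarray,
    sunset: np.ndarray,
    hours: np.ndarray,
    night_form: str = "forced",
) -> np.ndarray:
    """Vectorised hourly reconstruction for a contiguous run of days.

    Parameters are per-day arrays of equal length ``n``; ``hours`` is the
    evaluation grid in [0, 24].  Returns an ``(n, len(hours))`` array.
    Edge days reuse their own values as neighbour surrogates (first day:
    ``T_S,prev := T_S`` of itself; last day: ``Tn,next := Tn`` of itself),
    which keeps output length equal to input length.

    NaN minima/maxima propagate to the affected hours (including the
    neighbouring days' night branches); no imputation.
    """
    t_n = np.asarray(t_n, dtype=float)
    t_x = np.asarray(t_x, dtype=float)
    sunrise = np.asarray(sunrise, dtype=float)
    sunset = np.asarray(sunset, dtype=float)
    hours = np.asarray(hours, dtype=float)
    n = t_n.shape[0]
    if not (t_x.shape[0] == sunrise.shape[0] == sunset.shape[0] == n):
        raise ValueError("per-day arrays must have equal length")
    with np.errstate(invalid="ignore"):
        if np.any(t_n > t_x):
            raise ValueError("t_n > t_x on at least one day")
    if np.any(sunset - sunrise <= params.c) or np.any(
        sunset - sunrise + 2 * params.a - 2 * params.c <= 0
    ):
        raise ValueError("degenerate daylength for these parameters")

    t_s = _day_branch(params, t_n, t_x, sunrise, sunset, sunset)

    # neighbour context with edge-day surrogates
    t_s_prev = np.concatenate(([t_s[0]], t_s[:-1]))
    h_s_prev = np.concatenate(([sunset[0]], sunset[:-1]))
    t_n_next = np.concatenate((t_n[1:], [t_n[-1]]))
    h_r_next = np.concatenate((sunrise[1:], [sunrise[-1]]))

    n1 = sunrise - h_s_prev + params.c + 24.0
    n2 = h_r_next - sunset + params.c + 24.0
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("non-positive corrected night length")

    h = hours[np.newaxis, :]

    def col(v):
        return v[:, np.newaxis]

    morning = _night_branch(
        params, col(t_n), col(t_s_prev), h - col(h_s_prev) + 24.0, col(n1), night_form
    )
    day = _day_branch(params, col(t_n), col(t_x), col(sunrise), col(sunset), h)
    evening = _night_branch(
        params, col(t_n_next), col(t_s), h - col(sunset), col(n2), night_form
    )

    out = np.where(
        h < col(sunrise + params.c), morning, np.where(h <= col(sunset), day, evening)
    )
    return out


def hour_grid_values(hour_grid: str = "1-24") -> np.ndarray:
    """Evaluation hours for the two supported daily sampling conventions."""
    if hour_grid == "1-24":
        return np.arange(1.0, 25.0)
    if hour_grid == "0-23":
        return np.arange(0.0, 24.0)
    raise ValueError(f"hour_grid must be '1-24' or '0-23', got {hour_grid!r}")


def simulate_series(
    params: ModelParams,
    daily: pd.DataFrame,
    geometry: SiteGeometry,
    hour_grid: str = "1-24",
    hours: np.ndarray | None = None,
    night_form: str = "forced",
) -> pd.DataFrame:
    """Reconstruct an hourly temperature series from a daily Tn/Tx table.

    Parameters
    ----------
    daily : DataFrame
        Columns ``date`` (datetime-like, contiguous calendar days),
        ``tmin``, ``tmax`` in degC.  Missing values are allowed and
        propagate as NaN hours flagged ``missing``.
    hour_grid : str
        ``"1-24"`` (default; hour h stamps the end of the interval, matching
        degree-day summation over h = 1..24) or ``"0-23"``.
    hours : array, optional
        Explicit sub-hourly evaluation grid in [0, 24]; overrides
        ``hour_grid``.  Timestamps are ``date + hours``.

    Returns
    -------
    DataFrame with columns ``datetime``, ``temperature``, ``flag`` where
    ``flag`` is one of ``""``, ``"edge"`` (first/last day, neighbour
    surrogate in effect) or ``"missing"``.
    """
    daily = daily.reset_index(drop=True)
    if len(daily) < 2:
        raise ValueError("need at least two days to simulate")
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    deltas = dates.diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError("daily series has gaps or duplicated dates")
    t_n = daily["tmin"].to_numpy(dtype=float)
    t_x = daily["tmax"].to_numpy(dtype=float)

    doy = dates.dt.dayofyear.to_numpy()
    rise = sunrise_hours(geometry.latitude, doy)
    sets = 24.0 - rise

    grid = np.asarray(hours, dtype=float) if hours is not None else hour_grid_values(hour_grid)
    temps = diurnal_matrix(params, t_n, t_x, rise, sets, grid, night_form=night_form)

    n_days, n_hours = temps.shape
    stamp = (
        dates.to_numpy()[:, np.newaxis]
        + (grid * 3.6e12).astype("timedelta64[ns]")[np.newaxis, :]
    )
    flags = np.full((n_days, n_hours), "", dtype=object)
    flags[0, :] = "edge"
    flags[-1, :] = "edge"
    flags[np.isnan(temps)] = "missing"
    return pd.DataFrame(
        {
            "datetime": stamp.ravel(),
            "temperature": temps.ravel(),
            "flag": flags.ravel(),
        }
    )
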