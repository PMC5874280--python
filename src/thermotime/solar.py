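"""Solar geometry in true solar time (TST).

Everything downstream of this module runs on a decimal-hour clock that is
symmetric about solar noon: sunrise at ``12 - H/15`` and sunset at
``12 + H/15``, where ``H`` is the half-daylength hour angle in degrees.
Civil (mean local) time enters only through :func:`local_to_tst` /
:func:`tst_to_local` at the I/O boundary.

Declination and the equation of time use Spencer's Fourier series, which is
accurate to better than 0.3 degrees in declination and one minute in the
equation of time -- more than sufficient for diurnal-curve timing, where the
lag parameters themselves carry tens of minutes of uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteGeometry",
    "SolarTimes",
    "solar_declination",
    "equation_of_time",
    "sunrise_sunset",
    "local_to_tst",
    "tst_to_local",
    "potential_daily_radiation",
    "PolarDayNightError",
]

#: Solar constant, W m-2.
SOLAR_CONSTANT = 1367.0


class PolarDayNightError(ValueError):
    """Sun never rises or never sets on this day at this latitude."""


@dataclass(frozen=True)
class SiteGeometry:
    """Location of a station or grid cell.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    longitude : float
        Degrees east.
    standard_meridian : float
        Longitude (degrees east) defining the civil time zone, e.g. 15.0
        for CET.  Used only for the mean-local-time <-> TST conversion.
    elevation : float
        Metres above sea level.
    """

    latitude: float
    longitude: float = 0.0
    standard_meridian: float = 0.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if abs(self.longitude - self.standard_meridian) >= 30.0:
            raise ValueError(
                "longitude is more than 30 deg from the standard meridian; "
                "the TST offset would exceed two hours"
            )


@dataclass(frozen=True)
class SolarTimes:
    """Sunrise/sunset hours in decimal TST for one day.

    Invariant: ``sunrise + sunset == 24`` (symmetry about TST noon).
    """

    sunrise: float
    sunset: float
    day_of_year: int

    @property
    def daylength(self) -> float:
        return self.sunset - self.sunrise


def _day_angle(day_of_year):
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year must be in 1..366")
    return 2.0 * np.pi * (doy - 1.0) / 365.0


def solar_declination(day_of_year):
    """Solar declination (radians) from Spencer's Fourier series.

    Accepts scalars or arrays; result is bounded by +-23.45 degrees.
    """
    g = _day_angle(day_of_year)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )
    return decl if np.ndim(day_of_year) else float(decl)


def equation_of_time(day_of_year):
    """Equation of time in minutes (apparent minus mean solar time).

    Spencer's series; bounded within roughly [-15, +17] minutes over the
    year, with four zero crossings.
    """
    g = _day_angle(day_of_year)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return eot if np.ndim(day_of_year) else float(eot)


def _half_day_angle(latitude_deg, day_of_year):
    """Half-daylength hour angle H in radians; raises on polar day/night."""
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    delta = solar_declination(day_of_year)
    x = -np.tan(phi) * np.tan(np.asarray(delta))
    if np.any(x <= -1.0) or np.any(x >= 1.0):
        raise PolarDayNightError(
            "no sunrise/sunset: polar day or night at this latitude/DOY"
        )
    return np.arccos(x)


def sunrise_sunset(geometry: SiteGeometry, day_of_year: int) -> SolarTimes:
    """Sunrise and sunset hours (decimal TST) for a site and day of year.

    Raises
    ------
    PolarDayNightError
        Poleward of the polar circle for that day's declination.
    """
    h_deg = np.rad2deg(_half_day_angle(geometry.latitude, day_of_year))
    return SolarTimes(
        sunrise=float(12.0 - h_deg / 15.0),
        sunset=float(12.0 + h_deg / 15.0),
        day_of_year=int(day_of_year),
    )


def sunrise_hours(latitude_deg: float, day_of_year) -> np.ndarray:
    """Vectorised sunrise hour (TST) over an array of days of year."""
    h_deg = np.rad2deg(_half_day_angle(latitude_deg, day_of_year))
    return 12.0 - h_deg / 15.0


def local_to_tst(local_hour, geometry: SiteGeometry, day_of_year):
    """Convert mean local (civil) hour to true solar hour.

    TST = local + 4 min/deg * (longitude - standard meridian) + EoT,
    wrapped to [0, 24).
    """
    shift = (
        4.0 * (geometry.longitude - geometry.standard_meridian)
        + equation_of_time(day_of_year)
    ) / 60.0
    return np.mod(local_hour + shift, 24.0)


def tst_to_local(tst_hour, geometry: SiteGeometry, day_of_year):
    """Inverse of :func:`local_to_tst` (same day assumed)."""
    shift = (
        4.0 * (geometry.longitude - geometry.standard_meridian)
        + equation_of_time(day_of_year)
    ) / 60.0
    return np.mod(tst_hour - shift, 24.0)


def extraterrestrial_daily_radiation(geometry: SiteGeometry, day_of_year) -> float:
    """Daily total extraterrestrial radiation on a horizontal plane, MJ m-2 d-1.

    Standard closed form: (86400/pi) * Gsc * E0 *
    (cos(phi) cos(delta) sin(ws) + ws sin(phi) sin(delta)).
    Returns 0 (with a warning) during polar night.
    """
    phi = np.deg2rad(geometry.latitude)
    delta = solar_declination(day_of_year)
    e0 = 1.0 + 0.033 * np.cos(2.0 * np.pi * np.asarray(day_of_year) / 365.0)
    x = -np.tan(phi) * np.tan(delta)
    if np.ndim(x) == 0 and x >= 1.0:
        warnings.warn("polar night: extraterrestrial radiation is zero")
        return 0.0
    ws = np.arccos(np.clip(x, -1.0, 1.0))
    h0 = (
        (86400.0 / np.pi)
        * SOLAR_CONSTANT
        * e0
        * (np.cos(phi) * np.cos(delta) * np.sin(ws) + ws * np.sin(phi) * np.sin(delta))
    )
    return float(np.maximum(h0, 0.0) / 1.0e6)


def potential_daily_radiation(
    geometry: SiteGeometry, day_of_year, transmissivity: float = 0.75
) -> float:
    """Clear-sky potential daily global radiation, MJ m-2 d-1.

    Modelled as extraterrestrial daily radiation scaled by a constant
    atmospheric transmissivity (default 0.75).  The transmissivity is a free
    knob: it cancels out of any observed/potential ratio comparison as long
    as the same value is used to build the ratio threshold.
    """
    if not 0.0 < transmissivity <= 1.0:
        raise ValueError("transmissivity must be in (0, 1]")
    return transmissivity * extraterrestrial_daily_radiation(geometry, day_of_year)
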