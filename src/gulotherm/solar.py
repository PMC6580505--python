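"""Solar geometry for the study site: sun altitude, rise/set, civil twilight,
day length and polar-day/night regimes, plus meteorological season assignment.

A low-precision NOAA-style ephemeris (Fourier series for declination and the
equation of time) is used throughout; it is accurate to well under 0.3 deg in
altitude, which maps to a few minutes in event times — adequate for the
biologging context where events feed hour-scale summaries.

Sunrise/sunset are defined as the sun's *top edge* touching the horizon,
i.e. geometric centre altitude of -0.833 deg (16' semidiameter + 34'
standard refraction). Civil dawn/dusk are centre altitude -6 deg.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass

import numpy as np

#: centre altitude (deg) at which the top edge of the sun touches the horizon
SUNRISE_ALTITUDE_DEG = -0.833
#: centre altitude (deg) bounding civil twilight
CIVIL_TWILIGHT_ALTITUDE_DEG = -6.0


class SolarRegime(str, enum.Enum):
    NORMAL = "normal"
    POLAR_DAY = "polar_day"
    POLAR_NIGHT = "polar_night"


@dataclass(frozen=True)
class SolarDay:
    """Solar events for one calendar (UTC) date at a site."""

    date: dt.date
    latitude: float
    longitude: float
    sunrise: dt.datetime | None
    sunset: dt.datetime | None
    dawn: dt.datetime | None
    dusk: dt.datetime | None
    day_length_h: float
    regime: SolarRegime


def _frac_year(date: dt.date, hours_utc: float) -> float:
    doy = date.timetuple().tm_yday
    ndays = 366 if _is_leap(date.year) else 365
    return 2.0 * math.pi / ndays * (doy - 1 + (hours_utc - 12.0) / 24.0)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _decl_eqtime(gamma: float) -> tuple[float, float]:
    """Solar declination (rad) and equation of time (minutes)."""
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    return decl, eqtime


def solar_altitude(latitude: float, longitude: float, instant: dt.datetime) -> float:
    """Geometric altitude of the solar centre in degrees.

    ``instant`` must be timezone-aware or is assumed UTC. No refraction is
    applied; horizon definitions fold refraction into their altitude
    thresholds instead.
    """
    if abs(latitude) > 90.0:
        raise ValueError(f"latitude {latitude} out of range [-90, 90]")
    if instant.tzinfo is not None:
        instant = instant.astimezone(dt.timezone.utc).replace(tzinfo=None)
    hours = instant.hour + instant.minute / 60.0 + instant.second / 3600.0
    gamma = _frac_year(instant.date(), hours)
    decl, eqtime = _decl_eqtime(gamma)
    tst = hours * 60.0 + eqtime + 4.0 * longitude  # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)
    lat = math.radians(latitude)
    sin_alt = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))


def _altitude_grid(date: dt.date, latitude: float, longitude: float,
                   step_minutes: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Altitude sampled over the UTC day on a regular minute grid."""
    minutes = np.arange(0.0, 24.0 * 60.0 + step_minutes / 2, step_minutes)
    # gamma varies by < 2*pi/365 over a day; evaluate decl/eqtime per sample
    doy = date.timetuple().tm_yday
    ndays = 366 if _is_leap(date.year) else 365
    gammas = 2 * np.pi / ndays * (doy - 1 + (minutes / 60.0 - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(gammas)
        + 0.070257 * np.sin(gammas)
        - 0.006758 * np.cos(2 * gammas)
        + 0.000907 * np.sin(2 * gammas)
        - 0.002697 * np.cos(3 * gammas)
        + 0.00148 * np.sin(3 * gammas)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gammas)
        - 0.032077 * np.sin(gammas)
        - 0.014615 * np.cos(2 * gammas)
        - 0.040849 * np.sin(2 * gammas)
    )
    tst = minutes + eqtime + 4.0 * longitude
    ha = np.radians(tst / 4.0 - 180.0)
    lat = math.radians(latitude)
    sin_alt = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return minutes, np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))


def _refine_crossing(date: dt.date, latitude: float, longitude: float,
                     t_lo: float, t_hi: float, threshold: float) -> float:
    """Bisect a bracketed altitude crossing to ~1 s; times in UTC minutes."""
    def alt(m: float) -> float:
        instant = dt.datetime.combine(date, dt.time()) + dt.timedelta(minutes=m)
        return solar_altitude(latitude, longitude, instant) - threshold

    f_lo = alt(t_lo)
    for _ in range(40):
        mid = 0.5 * (t_lo + t_hi)
        f_mid = alt(mid)
        if (f_lo < 0) == (f_mid < 0):
            t_lo, f_lo = mid, f_mid
        else:
            t_hi = mid
        if t_hi - t_lo < 1.0 / 60.0:
            break
    return 0.5 * (t_lo + t_hi)


def _crossings(minutes: np.ndarray, alt: np.ndarray, threshold: float,
               date: dt.date, latitude: float, longitude: float
               ) -> tuple[list[float], list[float]]:
    above = alt >= threshold
    ups, downs = [], []
    flips = np.nonzero(above[1:] != above[:-1])[0]
    for i in flips:
        t = _refine_crossing(date, latitude, longitude,
                             minutes[i], minutes[i + 1], threshold)
        (ups if above[i + 1] else downs).append(t)
    return ups, downs


def sun_events(date: dt.date, latitude: float, longitude: float) -> SolarDay:
    """Sunrise/sunset, civil dawn/dusk, day length and regime for one date.

    Day length is the total time the solar centre is above -0.833 deg during
    the UTC day, which is robust under polar regimes and longitudes where a
    rise/set pair does not fall inside the same civil day.
    """
    minutes, alt = _altitude_grid(date, latitude, longitude)
    above = alt >= SUNRISE_ALTITUDE_DEG

    def to_instant(m: float) -> dt.datetime:
        return (dt.datetime.combine(date, dt.time(), tzinfo=dt.timezone.utc)
                + dt.timedelta(minutes=m))

    ups, downs = _crossings(minutes, alt, SUNRISE_ALTITUDE_DEG, date, latitude, longitude)
    dawn_ups, dusk_downs = _crossings(minutes, alt, CIVIL_TWILIGHT_ALTITUDE_DEG,
                                      date, latitude, longitude)

    if not ups and not downs:
        if bool(above[0]):
            return SolarDay(date, latitude, longitude, None, None,
                            None, None, 24.0, SolarRegime.POLAR_DAY)
        dawn = to_instant(dawn_ups[0]) if dawn_ups else None
        dusk = to_instant(dusk_downs[-1]) if dusk_downs else None
        return SolarDay(date, latitude, longitude, None, None,
                        dawn, dusk, 0.0, SolarRegime.POLAR_NIGHT)

    # integrate time above the horizon across the sampled day
    step = minutes[1] - minutes[0]
    day_length_h = float(np.count_nonzero(above[:-1]) * step) / 60.0
    # correct the trapezoid ends using refined crossing times
    boundary = sorted([(t, "up") for t in ups] + [(t, "down") for t in downs])
    day_len = 0.0
    t_prev, state = 0.0, bool(above[0])
    for t, kind in boundary:
        if state:
            day_len += t - t_prev
        t_prev, state = t, kind == "up"
    if state:
        day_len += 24.0 * 60.0 - t_prev
    day_length_h = day_len / 60.0

    sunrise = to_instant(ups[0]) if ups else None
    sunset = to_instant(downs[-1]) if downs else None
    dawn = to_instant(dawn_ups[0]) if dawn_ups else None
    dusk = to_instant(dusk_downs[-1]) if dusk_downs else None
    return SolarDay(date, latitude, longitude, sunrise, sunset,
                    dawn, dusk, day_length_h, SolarRegime.NORMAL)


def annual_day_lengths(year: int, latitude: float, longitude: float) -> "pd.DataFrame":
    """Day length (h) and regime for every date of ``year``; a DataFrame
    indexed by date with columns day_length_h, regime."""
    import pandas as pd

    dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
    rows = [sun_events(d.date(), latitude, longitude) for d in dates]
    return pd.DataFrame(
        {"day_length_h": [r.day_length_h for r in rows],
         "regime": [r.regime.value for r in rows]},
        index=[r.date for r in rows],
    )


_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(date: dt.date) -> str:
    """Meteorological season: winter Dec-Feb, spring Mar-May, summer Jun-Aug,
    autumn Sep-Nov."""
    return _SEASON_BY_MONTH[date.month]


def solar_table(year: int, latitude: float, longitude: float) -> "pd.DataFrame":
    """Per-date solar.csv-style table: sunrise, sunset, dawn, dusk,
    day_length_h, regime."""
    import pandas as pd

    dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
    recs = []
    for d in dates:
        s = sun_events(d.date(), latitude, longitude)
        recs.append({
            "date": s.date.isoformat(),
            "sunrise": s.sunrise.isoformat() if s.sunrise else "",
            "sunset": s.sunset.isoformat() if s.sunset else "",
            "dawn": s.dawn.isoformat() if s.dawn else "",
            "dusk": s.dusk.isoformat() if s.dusk else "",
            "day_length_h": round(s.day_length_h, 4),
            "regime": s.regime.value,
        })
    return pd.DataFrame.from_records(recs)
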