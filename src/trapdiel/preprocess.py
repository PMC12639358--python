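"""Circular-time conversion, temporal independence, and solar time bands.

The diel cycle is treated as the unit circle: a clock time t (minutes since
midnight) maps to the angle 2*pi*t/1440.  Each calendar month carries a mean
sunrise and sunset, which define four bands partitioning the cycle:

* Sunrise — one hour either side of mean sunrise,
* Sunset  — one hour either side of mean sunset,
* Day     — between the end of the Sunrise band and the start of Sunset,
* Night   — the remainder.

The crepuscular bands take precedence, so the four bands are mutually
exclusive and exhaustive (half-open ``[start, end)`` intervals).
"""
from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DetectionRecord, TWO_PI

__all__ = [
    "TimeBand", "SolarTable", "to_circular", "filter_independent",
    "assign_band", "band_availability", "daylight_fraction",
]

_MIN_PER_DAY = 1440.0
_CREPUSCULAR_HALF = 60.0  # minutes either side of the solar event


class TimeBand(enum.Enum):
    SUNRISE = "Sunrise"
    DAY = "Day"
    SUNSET = "Sunset"
    NIGHT = "Night"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def to_circular(clock_time: dt.time | float) -> float:
    """Map a clock time to its angle in radians on [0, 2*pi).

    Accepts a :class:`datetime.time` or minutes since midnight.
    """
    if isinstance(clock_time, dt.time):
        minutes = clock_time.hour * 60 + clock_time.minute + clock_time.second / 60
    else:
        minutes = float(clock_time)
    if not 0 <= minutes < _MIN_PER_DAY:
        raise ValueError(f"clock time out of range: {minutes} minutes")
    return TWO_PI * minutes / _MIN_PER_DAY


def _parse_hhmm(text: str) -> float:
    """'HH:MM' -> minutes since midnight."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"cannot parse clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"cannot parse clock time {text!r}")
    return 60.0 * h + m


@dataclass(frozen=True)
class SolarTable:
    """Monthly mean sunrise/sunset clock times (minutes since midnight)."""

    sunrise: Mapping[int, float]
    sunset: Mapping[int, float]

    def __post_init__(self) -> None:
        if set(self.sunrise) != set(self.sunset):
            raise ValueError("sunrise and sunset must cover the same months")
        for m in self.sunrise:
            if not 1 <= m <= 12:
                raise ValueError(f"invalid month {m}")
            if self.sunrise[m] >= self.sunset[m]:
                raise ValueError(f"month {m}: sunrise must precede sunset")
            if self.sunset[m] - self.sunrise[m] <= 2 * _CREPUSCULAR_HALF:
                raise ValueError(
                    f"month {m}: day shorter than the two crepuscular hours")

    @property
    def months(self) -> list[int]:
        return sorted(self.sunrise)

    @classmethod
    def from_csv(cls, path) -> "SolarTable":
        """Columns: month (1-12), sunrise (HH:MM), sunset (HH:MM)."""
        df = pd.read_csv(path)
        required = {"month", "sunrise", "sunset"}
        if not required <= set(df.columns):
            raise ValueError(f"solar CSV must have columns {sorted(required)}")
        return cls(
            sunrise={int(r.month): _parse_hhmm(str(r.sunrise)) for r in df.itertuples()},
            sunset={int(r.month): _parse_hhmm(str(r.sunset)) for r in df.itertuples()},
        )

    @classmethod
    def from_daily_csv(cls, path) -> "SolarTable":
        """Monthly means from a daily export with columns date, sunrise, sunset."""
        df = pd.read_csv(path)
        df["month"] = pd.to_datetime(df["date"]).dt.month
        df["sr"] = df["sunrise"].astype(str).map(_parse_hhmm)
        df["ss"] = df["sunset"].astype(str).map(_parse_hhmm)
        g = df.groupby("month")[["sr", "ss"]].mean()
        return cls(sunrise=g["sr"].to_dict(), sunset=g["ss"].to_dict())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"month": m,
                 "sunrise": f"{int(self.sunrise[m]) // 60:02d}:{int(self.sunrise[m]) % 60:02d}",
                 "sunset": f"{int(self.sunset[m]) // 60:02d}:{int(self.sunset[m]) % 60:02d}"}
                for m in self.months]
        return pd.DataFrame(rows)


def filter_independent(records: Sequence[DetectionRecord],
                       interval: dt.timedelta | int = 60,
                       ) -> list[DetectionRecord]:
    """Greedy temporal-independence filter.

    Within each (site, species) stream, a record is retained iff it falls at
    least ``interval`` after the last *retained* record of that stream; the
    first record of every stream is always retained.  Input must already be
    sorted by timestamp within each stream.

    Parameters
    ----------
    interval : timedelta or minutes
        Minimum spacing between retained records (default one hour).
    """
    if isinstance(interval, (int, float)):
        interval = dt.timedelta(minutes=interval)
    last_kept: dict[tuple[str, str], dt.datetime] = {}
    last_seen: dict[tuple[str, str], dt.datetime] = {}
    kept: list[DetectionRecord] = []
    for rec in records:
        key = (rec.site_id, rec.species)
        if key in last_seen and rec.timestamp < last_seen[key]:
            raise ValueError(
                f"records not sorted within stream {key}: "
                f"{rec.timestamp} after {last_seen[key]}")
        last_seen[key] = rec.timestamp
        if key not in last_kept or rec.timestamp - last_kept[key] >= interval:
            kept.append(rec)
            last_kept[key] = rec.timestamp
    return kept


def _band_of_minutes(minutes: float, sunrise: float, sunset: float) -> TimeBand:
    h = _CREPUSCULAR_HALF
    if (sunrise - h) <= minutes < (sunrise + h):
        return TimeBand.SUNRISE
    if (sunset - h) <= minutes < (sunset + h):
        return TimeBand.SUNSET
    if (sunrise + h) <= minutes < (sunset - h):
        return TimeBand.DAY
    return TimeBand.NIGHT


def assign_band(when: dt.datetime | tuple[float, dt.date],
                solar: SolarTable) -> TimeBand:
    """Assign the solar time band of a detection.

    ``when`` is either a datetime or a ``(angle_radians, date)`` pair; the
    date selects the month whose mean sunrise/sunset define the bands.
    """
    if isinstance(when, dt.datetime):
        minutes = when.hour * 60 + when.minute + when.second / 60
        month = when.month
    else:
        angle, date = when
        minutes = (angle % TWO_PI) / TWO_PI * _MIN_PER_DAY
        month = date.month
    if month not in solar.sunrise:
        raise KeyError(f"month {month} absent from solar table")
    return _band_of_minutes(minutes, solar.sunrise[month], solar.sunset[month])


def band_availability(solar: SolarTable,
                      month_weights: Mapping[int, float] | None = None,
                      ) -> dict[TimeBand, float]:
    """Fraction of the diel cycle occupied by each band.

    Per month: Sunrise and Sunset each cover 2 h / 24 h; Day covers the
    daylight span minus the two crepuscular hours; Night the remainder.
    With ``month_weights`` (e.g. detection-days per month) the monthly
    availabilities are averaged with those weights; default is uniform over
    the months in the table.  The result sums to one.
    """
    months = solar.months
    if month_weights is None:
        weights = {m: 1.0 / len(months) for m in months}
    else:
        total = float(sum(month_weights.values()))
        if total <= 0:
            raise ValueError("month weights must have positive sum")
        unknown = set(month_weights) - set(months)
        if unknown:
            raise KeyError(f"weights given for months absent from solar table: {sorted(unknown)}")
        weights = {m: month_weights.get(m, 0.0) / total for m in months}
    out = {b: 0.0 for b in TimeBand}
    for m in months:
        day_min = (solar.sunset[m] - solar.sunrise[m]) - 2 * _CREPUSCULAR_HALF
        p_day = day_min / _MIN_PER_DAY
        p_crep = 2 * _CREPUSCULAR_HALF / _MIN_PER_DAY
        p_night = 1.0 - p_day - 2 * p_crep
        w = weights[m]
        out[TimeBand.SUNRISE] += w * p_crep
        out[TimeBand.SUNSET] += w * p_crep
        out[TimeBand.DAY] += w * p_day
        out[TimeBand.NIGHT] += w * p_night
    return out


def daylight_fraction(angles: Iterable[float], dates: Iterable[dt.date],
                      solar: SolarTable, include_crepuscular: bool = True,
                      ) -> float:
    """Proportion of detections falling between sunrise and sunset.

    With ``include_crepuscular`` (default) daylight is the full
    sunrise-to-sunset window; otherwise the crepuscular hours are excluded,
    counting only the Day band.
    """
    angles = list(angles)
    dates = list(dates)
    if len(angles) != len(dates):
        raise ValueError("angles and dates must be parallel")
    if not angles:
        raise ValueError("empty sample")
    n_day = 0
    for a, d in zip(angles, dates):
        if d.month not in solar.sunrise:
            raise KeyError(f"month {d.month} absent from solar table")
        minutes = (a % TWO_PI) / TWO_PI * _MIN_PER_DAY
        if include_crepuscular:
            if solar.sunrise[d.month] <= minutes < solar.sunset[d.month]:
                n_day += 1
        else:
            if _band_of_minutes(minutes, solar.sunrise[d.month],
                                solar.sunset[d.month]) is TimeBand.DAY:
                n_day += 1
    return n_day / len(angles)
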