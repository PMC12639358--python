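"""Core in-memory types: detections, deployments, traits, calendars, samples."""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

VALID_ACTIVITY = ("diurnal", "mostly diurnal", "cathemeral",
                  "mostly nocturnal", "nocturnal")
VALID_DIET = ("herbivore", "omnivore", "carnivore")

__all__ = [
    "DetectionRecord", "DeploymentLog", "TraitTable", "TouristCalendar",
    "DielSample", "VALID_ACTIVITY", "VALID_DIET",
]


@dataclass(frozen=True, order=True)
class DetectionRecord:
    """One camera-trap event: who, where, when, how many."""

    site_id: str
    species: str
    timestamp: dt.datetime
    n_individuals: int = 1
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass(frozen=True)
class DeploymentLog:
    """Operational intervals per camera site; effort in trap-days.

    ``active_intervals`` maps ``site_id`` to a list of inclusive
    ``(first_day, last_day)`` date ranges during which the camera ran.
    """

    active_intervals: Mapping[str, Sequence[tuple[dt.date, dt.date]]]

    def __post_init__(self) -> None:
        for site, spans in self.active_intervals.items():
            spans = sorted(spans)
            for (a0, a1) in spans:
                if a1 < a0:
                    raise ValueError(f"site {site}: interval end before start")
            for (_, prev_end), (next_start, _) in zip(spans, spans[1:]):
                if next_start <= prev_end:
                    raise ValueError(f"site {site}: overlapping intervals")

    @classmethod
    def continuous(cls, site_ids: Iterable[str], first_day: dt.date,
                   n_days: int) -> "DeploymentLog":
        """Every camera active for the same uninterrupted block of days."""
        last = first_day + dt.timedelta(days=n_days - 1)
        return cls({s: [(first_day, last)] for s in site_ids})

    def trap_days(self) -> int:
        """Total survey effort: one unit per camera per operational day."""
        total = 0
        for spans in self.active_intervals.values():
            for a0, a1 in spans:
                total += (a1 - a0).days + 1
        return total

    def units(self) -> list[tuple[str, dt.date]]:
        """All (site, date) sampling units, ordered by site then date."""
        out: list[tuple[str, dt.date]] = []
        for site in sorted(self.active_intervals):
            for a0, a1 in sorted(self.active_intervals[site]):
                d = a0
                while d <= a1:
                    out.append((site, d))
                    d += dt.timedelta(days=1)
        return out

    def is_active(self, site: str, day: dt.date) -> bool:
        for a0, a1 in self.active_intervals.get(site, ()):
            if a0 <= day <= a1:
                return True
        return False


@dataclass(frozen=True)
class TraitTable:
    """Per-species activity cycle and trophic level.

    These stand in for the literature/database classifications used for
    species too rarely detected to classify from their own data.
    """

    activity: Mapping[str, str]
    diet: Mapping[str, str]

    def __post_init__(self) -> None:
        for sp, a in self.activity.items():
            if a not in VALID_ACTIVITY:
                raise ValueError(f"{sp}: invalid activity cycle {a!r}")
        for sp, d in self.diet.items():
            if d not in VALID_DIET:
                raise ValueError(f"{sp}: invalid diet {d!r}")

    def require(self, species: Iterable[str]) -> None:
        missing = [s for s in species
                   if s not in self.activity or s not in self.diet]
        if missing:
            raise KeyError(f"species missing from trait table: {sorted(set(missing))}")


@dataclass(frozen=True)
class TouristCalendar:
    """Day-level labels: were tourists present in the protected area?"""

    presence: Mapping[dt.date, bool]

    def tourists_present(self, day: dt.date) -> bool:
        try:
            return self.presence[day]
        except KeyError:
            raise KeyError(f"date {day} not covered by the tourist calendar") from None

    def n_days(self) -> tuple[int, int]:
        """(days with tourists, days without)."""
        vals = list(self.presence.values())
        return sum(vals), len(vals) - sum(vals)

    def validate_covers(self, records: Iterable[DetectionRecord]) -> None:
        missing = sorted({r.timestamp.date() for r in records} - set(self.presence))
        if missing:
            raise KeyError(f"detection dates missing from tourist calendar: {missing[:5]}")


@dataclass
class DielSample:
    """Detection times of one analysis unit as angles on the 24-h circle."""

    label: str
    records: list[DetectionRecord] = field(default_factory=list)
    class_label: str = "pooled"

    def __post_init__(self) -> None:
        from .preprocess import to_circular  # local import avoids a cycle
        self._to_circular = to_circular

    @property
    def angles(self) -> np.ndarray:
        """Detection times in radians, [0, 2*pi)."""
        return np.array([self._to_circular(r.timestamp.time())
                         for r in self.records], dtype=float)

    @property
    def dates(self) -> list[dt.date]:
        return [r.timestamp.date() for r in self.records]

    def __len__(self) -> int:
        return len(self.records)
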