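"""Jacobs electivity for solar time bands and data-driven activity classes.

Selection of a time band compares the proportion of a species' independent
detections in the band (use, r) with the band's share of the diel cycle
(availability, p) through Jacobs' index

    D = (r - p) / (r + p - 2 r p),

bounded on [-1, 1]: -1 complete avoidance, 0 use in proportion to
availability, +1 exclusive use.  Uncertainty comes from resampling the
detections with replacement and recomputing the index.
"""
from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import AnalysisConfig
from .preprocess import (SolarTable, TimeBand, assign_band, band_availability,
                         daylight_fraction)
from .records import DielSample

__all__ = ["JacobsResult", "jacobs_index", "bootstrap_selectivity",
           "classify_activity"]


def jacobs_index(r: float, p: float) -> float:
    """Jacobs' modified electivity index D = (r - p)/(r + p - 2rp)."""
    if not 0 <= r <= 1:
        raise ValueError("use proportion r must lie in [0, 1]")
    if not 0 < p < 1:
        raise ValueError("availability p must lie strictly in (0, 1)")
    return (r - p) / (r + p - 2 * r * p)


@dataclass(frozen=True)
class JacobsResult:
    """Per-band electivity of one species or group."""

    species: str
    n: int
    use: Mapping[TimeBand, float]
    availability: Mapping[TimeBand, float]
    index: Mapping[TimeBand, float]
    boot_mean: Mapping[TimeBand, float]
    boot_ci: Mapping[TimeBand, tuple[float, float]]

    def summary(self) -> str:
        lines = [f"Jacobs electivity: {self.species} (n={self.n} independent detections)"]
        for band in TimeBand:
            lo, hi = self.boot_ci[band]
            lines.append(
                f"  {band.value:<8} r={self.use[band]:.3f} "
                f"p={self.availability[band]:.3f} D={self.index[band]:+.3f} "
                f"boot mean {self.boot_mean[band]:+.3f} [{lo:+.3f}, {hi:+.3f}]")
        return "\n".join(lines)


def bootstrap_selectivity(sample: DielSample, solar: SolarTable,
                          reps: int = 10_000,
                          seed: int | np.random.Generator = 0,
                          level: float = 0.95,
                          month_weights: Mapping[int, float] | None = None,
                          ) -> JacobsResult:
    """Band-wise Jacobs D with bootstrap mean and percentile CI.

    Each replicate resamples the detections with replacement (same n),
    recomputes the band-use proportions and the index per band.  Band
    availability defaults to weighting months by the sample's detections.
    """
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bands = [assign_band((a, d), solar)
             for a, d in zip(sample.angles, sample.dates)]
    if month_weights is None:
        month_weights = dict(Counter(d.month for d in sample.dates))
    p = band_availability(solar, month_weights)
    for band in TimeBand:
        if not 0 < p[band] < 1:
            raise ValueError(f"band {band.value} has degenerate availability {p[band]}")
    band_order = list(TimeBand)
    counts = np.array([sum(b is band for b in bands) for band in band_order], float)
    r = counts / n
    p_vec = np.array([p[band] for band in band_order])
    d_point = np.clip((r - p_vec) / (r + p_vec - 2 * r * p_vec), -1.0, 1.0)

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # resampling detections with replacement == multinomial over band counts
    boot_counts = rng.multinomial(n, counts / n, size=reps).astype(float)
    rb = boot_counts / n
    d_boot = np.clip((rb - p_vec) / (rb + p_vec - 2 * rb * p_vec), -1.0, 1.0)
    alpha = 1 - level
    lo, hi = np.percentile(d_boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return JacobsResult(
        species=sample.label, n=n,
        use={band: float(r[i]) for i, band in enumerate(band_order)},
        availability={band: float(p_vec[i]) for i, band in enumerate(band_order)},
        index={band: float(d_point[i]) for i, band in enumerate(band_order)},
        boot_mean={band: float(d_boot[:, i].mean()) for i, band in enumerate(band_order)},
        boot_ci={band: (float(lo[i]), float(hi[i])) for i, band in enumerate(band_order)},
    )


def classify_activity(sample: DielSample, solar: SolarTable,
                      breaks: Sequence[float] = (0.10, 0.30, 0.70, 0.90),
                      include_crepuscular: bool = True) -> str:
    """Activity-cycle label from the proportion of daylight detections.

    With daylight proportion q and breaks (b1, b2, b3, b4):
    nocturnal (q < b1), mostly nocturnal (b1 <= q < b2), cathemeral
    (b2 <= q < b3), mostly diurnal (b3 <= q < b4), diurnal (q >= b4).
    Intended for species with enough detections to classify from data;
    rarer species should keep their literature trait label.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    b1, b2, b3, b4 = breaks
    q = daylight_fraction(sample.angles, sample.dates, solar,
                          include_crepuscular=include_crepuscular)
    if q < b1:
        return "nocturnal"
    if q < b2:
        return "mostly nocturnal"
    if q < b3:
        return "cathemeral"
    if q < b4:
        return "mostly diurnal"
    return "diurnal"
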