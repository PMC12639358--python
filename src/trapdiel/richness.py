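"""Randomised species accumulation curves from camera-trap incidence.

The sampling unit is the camera-trap-day: one camera operational for one
calendar day.  Units are added in random order, the cumulative number of
distinct species recorded is tracked, and the mean and a percentile band
across permutations form the accumulation curve.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .records import DeploymentLog, DetectionRecord

__all__ = ["AccumulationCurve", "build_incidence", "accumulation_curve",
           "expected_richness"]


def build_incidence(records: Sequence[DetectionRecord],
                    deployments: DeploymentLog,
                    unit: Literal["trap-day", "site", "detection"] = "trap-day",
                    ) -> pd.DataFrame:
    """Binary incidence matrix (sampling unit x species).

    ``unit`` selects the sampling unit: one camera-trap-day (default), one
    site pooled over its whole deployment, or one detection.  For trap-day
    units every record's (site, date) must fall inside an active deployment
    interval.
    """
    species = sorted({r.species for r in records})
    if unit == "trap-day":
        units = deployments.units()
        offenders = [(r.site_id, r.timestamp.date()) for r in records
                     if not deployments.is_active(r.site_id, r.timestamp.date())]
        if offenders:
            raise ValueError(f"records outside deployment intervals: "
                             f"{sorted(set(offenders))[:5]}")
        index = pd.MultiIndex.from_tuples(units, names=["site", "date"])
        mat = pd.DataFrame(0, index=index, columns=species, dtype=np.int8)
        for r in records:
            mat.loc[(r.site_id, r.timestamp.date()), r.species] = 1
    elif unit == "site":
        sites = sorted(deployments.active_intervals)
        mat = pd.DataFrame(0, index=pd.Index(sites, name="site"),
                           columns=species, dtype=np.int8)
        for r in records:
            mat.loc[r.site_id, r.species] = 1
    elif unit == "detection":
        mat = pd.DataFrame(0, index=pd.RangeIndex(len(records), name="detection"),
                           columns=species, dtype=np.int8)
        for i, r in enumerate(records):
            mat.iloc[i, species.index(r.species)] = 1
    else:
        raise ValueError(f"unknown sampling unit {unit!r}")
    return mat


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean cumulative richness by effort, with a confidence band."""

    effort: np.ndarray
    mean_richness: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    permutations: int
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"effort": self.effort,
                             "mean_richness": self.mean_richness,
                             "ci_lo": self.ci_lo, "ci_hi": self.ci_hi})

    def plot(self, ax=None):
        """Accumulation curve with its confidence band, one point per unit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.effort, self.ci_lo, self.ci_hi,
                        color="grey", alpha=0.4,
                        label=f"{100 * self.level:.0f}% band")
        ax.plot(self.effort, self.mean_richness, color="black", label="mean")
        ax.set_xlabel("sampling effort (trap-days)")
        ax.set_ylabel("cumulative species")
        ax.legend()
        return ax


def accumulation_curve(incidence: pd.DataFrame | np.ndarray,
                       permutations: int = 1000, level: float = 0.95,
                       seed: int | np.random.Generator = 0,
                       band: Literal["percentile", "sd"] = "percentile",
                       ) -> AccumulationCurve:
    """Randomised species accumulation curve.

    For each permutation the unit order is shuffled and the cumulative count
    of distinct species recorded; the curve reports the across-permutation
    mean with a percentile band (or mean ± 1.96 sd with ``band="sd"``).
    """
    mat = np.asarray(incidence, dtype=bool)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("incidence must be a 2-D matrix with >= 2 units")
    k, s = mat.shape
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    curves = np.empty((permutations, k), dtype=np.int32)
    for p in range(permutations):
        order = rng.permutation(k)
        seen = np.maximum.accumulate(mat[order], axis=0)
        curves[p] = seen.sum(axis=1)
    mean = curves.mean(axis=0)
    if band == "percentile":
        alpha = 1 - level
        lo, hi = np.percentile(curves, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                               axis=0)
    elif band == "sd":
        sd = curves.std(axis=0, ddof=1)
        lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    else:
        raise ValueError(f"unknown band type {band!r}")
    return AccumulationCurve(effort=np.arange(1, k + 1), mean_richness=mean,
                             ci_lo=lo, ci_hi=hi, permutations=permutations,
                             level=level)


def expected_richness(incidence: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Exact expectation of the accumulation curve under random unit order.

    E[S_k] = sum_j (1 - C(N - n_j, k) / C(N, k)) with N units and species j
    present in n_j of them — the hypergeometric (sample-based rarefaction)
    form, used as an independent check on the randomised curve.
    """
    mat = np.asarray(incidence, dtype=bool)
    n_units, _ = mat.shape
    n_j = mat.sum(axis=0)
    ks = np.arange(1, n_units + 1)
    out = np.zeros(n_units)
    # work with log-gammas: C(N-n_j, k)/C(N, k) underflows comfortably
    from scipy.special import gammaln

    def log_comb(n, k):
        n, k = np.asarray(n, float), np.asarray(k, float)
        bad = (k > n) | (k < 0)
        val = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return np.where(bad, -np.inf, val)

    for j, nj in enumerate(n_j):
        if nj == 0:
            continue
        log_p_absent = log_comb(n_units - nj, ks) - log_comb(n_units, ks)
        out += 1.0 - np.exp(log_p_absent)
    return out
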