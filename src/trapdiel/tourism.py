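"""End-to-end tourism-impact comparison of diel activity patterns.

:class:`TourismStudy` is the top-level model object: built from detections,
a solar table, a tourist calendar and species traits, its :meth:`fit` runs
the whole comparison — temporal-independence filtering, unit construction
(abundant species, whole community, diel guilds, trophic groups), the
with/without-tourists split, overlap estimation with smoothed-bootstrap CIs,
two-sample Watson tests and percentile classification — and returns a
:class:`TourismReport`.
"""
from __future__ import annotations

import datetime as dt
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import watson_uniformity
from .config import AnalysisConfig
from .io import read_calendar, read_detections, read_traits, write_results
from .overlap import OverlapModel, OverlapResults, classify_overlaps
from .preprocess import SolarTable, TimeBand, filter_independent
from .records import (DetectionRecord, DielSample, TouristCalendar, TraitTable)
from .selectivity import bootstrap_selectivity, classify_activity

__all__ = ["AnalysisUnit", "TourismStudy", "TourismReport",
           "build_units", "split_by_calendar"]

_DIET_PLURAL = {"herbivore": "herbivores", "omnivore": "omnivores",
                "carnivore": "carnivores"}
# pooling order for under-detected trophic groups: each maps to its nearest
# neighbour along the trophic gradient
_TROPHIC_NEIGHBOUR = {"carnivore": "omnivore", "omnivore": "herbivore",
                      "herbivore": "omnivore"}


@dataclass(frozen=True)
class AnalysisUnit:
    """One comparison unit: a species or a pooled species group."""

    name: str
    member_species: frozenset[str]
    selection_rule: str  # abundant_species | whole_community | diel_guild | trophic_group
    pooled: bool

    def __post_init__(self) -> None:
        if not self.member_species:
            raise ValueError(f"unit {self.name}: member species must be non-empty")


def split_by_calendar(sample: DielSample, calendar: TouristCalendar,
                      ) -> tuple[DielSample, DielSample]:
    """Partition one unit's detections into tourist-present/absent samples."""
    present, absent = [], []
    for rec in sample.records:
        if calendar.tourists_present(rec.timestamp.date()):
            present.append(rec)
        else:
            absent.append(rec)
    return (DielSample(sample.label, present, class_label="tourists present"),
            DielSample(sample.label, absent, class_label="tourists absent"))


def build_units(records: Sequence[DetectionRecord], traits: TraitTable,
                config: AnalysisConfig | None = None,
                activity_labels: Mapping[str, str] | None = None,
                ) -> list[AnalysisUnit]:
    """Construct the comparison units from independent detections.

    Units: each species with more than ``abundance_threshold`` detections;
    the whole community; one pooled unit per diel guild (nocturnal pools
    nocturnal + mostly nocturnal, diurnal pools diurnal + mostly diurnal,
    cathemeral species belong to no guild); trophic groups, pooling any
    group under ``trophic_min_detections`` into its neighbour (carnivores
    into omnivores).  ``activity_labels`` overrides the trait-table activity
    cycle per species (e.g. data-driven labels for abundant species).
    """
    config = config or AnalysisConfig()
    counts = Counter(r.species for r in records)
    if not counts:
        raise ValueError("no detections to build units from")
    traits.require(counts)
    labels = dict(traits.activity)
    if activity_labels:
        labels.update(activity_labels)

    units: list[AnalysisUnit] = []
    for sp, n in sorted(counts.items()):
        if n > config.abundance_threshold:
            units.append(AnalysisUnit(sp, frozenset([sp]), "abundant_species", False))
    units.append(AnalysisUnit("whole community", frozenset(counts),
                              "whole_community", True))
    guilds = {
        "diurnal species": {sp for sp in counts
                            if labels[sp] in ("diurnal", "mostly diurnal")},
        "nocturnal species": {sp for sp in counts
                              if labels[sp] in ("nocturnal", "mostly nocturnal")},
    }
    any_guild = False
    for name, members in guilds.items():
        if members:
            units.append(AnalysisUnit(name, frozenset(members), "diel_guild", True))
            any_guild = True
    if not any_guild:
        warnings.warn("no diurnal or nocturnal species; no diel-guild units built")

    trophic: dict[frozenset[str], set[str]] = {}
    for diet in ("herbivore", "omnivore", "carnivore"):
        members = {sp for sp in counts if traits.diet[sp] == diet}
        if members:
            trophic[frozenset([diet])] = members
    # pool under-detected groups into their trophic neighbour
    changed = True
    while changed and len(trophic) > 1:
        changed = False
        for diets, members in sorted(trophic.items(),
                                     key=lambda kv: sorted(kv[0])):
            n = sum(counts[sp] for sp in members)
            if n >= config.trophic_min_detections:
                continue
            for diet in sorted(diets):
                target = _TROPHIC_NEIGHBOUR[diet]
                home = next((k for k in trophic if target in k and k != diets), None)
                if home is not None:
                    trophic[home | diets] = trophic.pop(home) | trophic.pop(diets)
                    changed = True
                    break
            if changed:
                break
    for diets, members in sorted(trophic.items(), key=lambda kv: sorted(kv[0])):
        order = [d for d in ("herbivore", "omnivore", "carnivore") if d in diets]
        name = " and ".join(_DIET_PLURAL[d] for d in order)
        units.append(AnalysisUnit(name, frozenset(members), "trophic_group",
                                  len(members) > 1))
    return units


@dataclass
class TourismReport:
    """Results of the full tourism comparison."""

    results: list[OverlapResults]
    skipped: list[tuple[str, int, int]]   # unit, n_present, n_absent
    units: list[AnalysisUnit]
    activity_table: pd.DataFrame
    overlap_table: pd.DataFrame
    metadata: dict

    def summary(self) -> str:
        lines = ["Tourism impact on diel activity", "=" * 34,
                 f"independent detections: {self.metadata['n_independent']} "
                 f"(of {self.metadata['n_raw']} raw)",
                 f"tourist days: {self.metadata['tourist_days']} present / "
                 f"{self.metadata['nontourist_days']} absent", ""]
        header = (f"{'unit':<28}{'n+':>5}{'n-':>5}  {'est':<6}"
                  f"{'Delta':>6}  {'95% CI':<15}{'U2':>7}{'p':>8}  class")
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.results:
            ci = f"[{r.ci[0]:.2f}, {r.ci[1]:.2f}]" if r.ci else "-"
            u2 = f"{r.watson.statistic:.3f}" if r.watson else "-"
            p = f"{r.watson.p_value:.3f}" if r.watson else "-"
            lines.append(f"{r.unit:<28}{r.n_a:>5}{r.n_b:>5}  {r.estimator:<6}"
                         f"{r.delta:>6.3f}  {ci:<15}{u2:>7}{p:>8}  "
                         f"{r.classification or '-'}")
        for name, np_, na_ in self.skipped:
            lines.append(f"{name:<28}{np_:>5}{na_:>5}  skipped (class below "
                         f"minimum n)")
        return "\n".join(lines)

    @property
    def n_significant(self) -> int:
        return sum(1 for r in self.results
                   if r.watson is not None and r.watson.significant)

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        tables = {"activity_summary": self.activity_table,
                  "tourism_overlap": self.overlap_table}
        if fmt == "csv":
            write_results(tables, out_dir, fmt="csv",
                          config=self.metadata.get("config_obj"),
                          seed=self.metadata.get("seed"))
        else:
            write_results(tables, Path(out_dir) / "report.json", fmt="json",
                          config=self.metadata.get("config_obj"),
                          seed=self.metadata.get("seed"))


class TourismStudy:
    """Model object for the tourism comparison (construct, then ``fit``)."""

    def __init__(self, records: Sequence[DetectionRecord], solar: SolarTable,
                 calendar: TouristCalendar, traits: TraitTable,
                 config: AnalysisConfig | None = None):
        self.records = list(records)
        if not self.records:
            raise ValueError("no detections supplied")
        self.solar = solar
        self.calendar = calendar
        self.traits = traits
        self.config = config or AnalysisConfig()
        calendar.validate_covers(self.records)
        traits.require({r.species for r in self.records})

    @classmethod
    def from_csv(cls, detections: str | Path, solar: str | Path,
                 calendar: str | Path, traits: str | Path,
                 config: AnalysisConfig | None = None) -> "TourismStudy":
        return cls(records=read_detections(detections),
                   solar=SolarTable.from_csv(solar),
                   calendar=read_calendar(calendar),
                   traits=read_traits(traits), config=config)

    @classmethod
    def from_survey(cls, survey, config: AnalysisConfig | None = None,
                    ) -> "TourismStudy":
        """Build directly from a :class:`~trapdiel.simulate.SyntheticSurvey`."""
        return cls(records=survey.records, solar=survey.solar,
                   calendar=survey.calendar, traits=survey.traits,
                   config=config)

    def fit(self, seed: int | None = None, bootstrap_reps: int | None = None,
            compute_ci: bool = True, reclassify_abundant: bool = False,
            ) -> TourismReport:
        """Run the full pipeline and return a :class:`TourismReport`.

        ``seed`` overrides the config's ``rng_seed``; ``bootstrap_reps``
        overrides the config's replicate count for electivity and CIs.
        With ``reclassify_abundant`` the abundant species' activity labels
        are re-derived from their own detections (disagreements with the
        trait table are warned about) before guild construction.
        """
        cfg = self.config
        seed = cfg.rng_seed if seed is None else seed
        reps = cfg.bootstrap_reps if bootstrap_reps is None else bootstrap_reps
        seeds = np.random.SeedSequence(seed).spawn(3)
        rng_selectivity = np.random.default_rng(seeds[0])
        rng_ci = np.random.default_rng(seeds[1])

        independent = filter_independent(self.records,
                                         cfg.independence_interval_min)
        by_species: dict[str, DielSample] = {}
        for rec in independent:
            by_species.setdefault(rec.species, DielSample(rec.species, []))
        for rec in independent:
            by_species[rec.species].records.append(rec)

        activity_labels: dict[str, str] = {}
        if reclassify_abundant:
            for sp, sample in by_species.items():
                if len(sample) > cfg.abundance_threshold:
                    label = classify_activity(sample, self.solar,
                                              cfg.activity_class_breaks)
                    if label != self.traits.activity[sp]:
                        warnings.warn(f"{sp}: data-driven activity {label!r} "
                                      f"disagrees with trait table "
                                      f"{self.traits.activity[sp]!r}")
                    activity_labels[sp] = label

        units = build_units(independent, self.traits, cfg,
                            activity_labels=activity_labels)

        activity_rows = []
        raw_counts = Counter(r.species for r in self.records)
        for sp in sorted(by_species, key=lambda s: -len(by_species[s])):
            sample = by_species[sp]
            row = {"species": sp, "total_detections": raw_counts[sp],
                   "independent_detections": len(sample),
                   "d_sunrise": np.nan, "d_day": np.nan, "d_sunset": np.nan,
                   "d_night": np.nan, "u2": np.nan, "u2_p": np.nan,
                   "activity_cycle": activity_labels.get(
                       sp, self.traits.activity[sp]),
                   "diet": self.traits.diet[sp]}
            if len(sample) > cfg.abundance_threshold:
                jac = bootstrap_selectivity(sample, self.solar, reps=reps,
                                            seed=rng_selectivity)
                row.update({"d_sunrise": jac.boot_mean[TimeBand.SUNRISE],
                            "d_day": jac.boot_mean[TimeBand.DAY],
                            "d_sunset": jac.boot_mean[TimeBand.SUNSET],
                            "d_night": jac.boot_mean[TimeBand.NIGHT]})
            if len(sample) >= 8:
                w = watson_uniformity(sample.angles)
                row["u2"] = w.statistic
                row["u2_p"] = w.p_value
            activity_rows.append(row)

        results: list[OverlapResults] = []
        skipped: list[tuple[str, int, int]] = []
        for unit in units:
            members = unit.member_species
            recs = [r for r in independent if r.species in members]
            pooled = DielSample(unit.name, recs)
            present, absent = split_by_calendar(pooled, self.calendar)
            if min(len(present), len(absent)) < cfg.min_class_n:
                skipped.append((unit.name, len(present), len(absent)))
                continue
            model = OverlapModel(present.angles, absent.angles,
                                 unit=unit.name, config=cfg)
            results.append(model.fit(reps=reps, seed=rng_ci,
                                     compute_ci=compute_ci))
        classify_overlaps(results, cfg.percentile_breaks)

        overlap_table = pd.DataFrame(
            [{"unit": r.unit, "n_present": r.n_a, "n_absent": r.n_b,
              "estimator": r.estimator, "delta": r.delta,
              "lo": r.ci[0] if r.ci else np.nan,
              "hi": r.ci[1] if r.ci else np.nan,
              "u2": r.watson.statistic if r.watson else np.nan,
              "u2_p": r.watson.p_value if r.watson else np.nan,
              "class": r.classification} for r in results])
        n_t, n_nt = self.calendar.n_days()
        metadata = {"seed": seed, "config_hash": cfg.config_hash(),
                    "config_obj": cfg, "n_raw": len(self.records),
                    "n_independent": len(independent),
                    "tourist_days": n_t, "nontourist_days": n_nt,
                    "n_units": len(units), "n_skipped": len(skipped)}
        return TourismReport(results=results, skipped=skipped, units=units,
                             activity_table=pd.DataFrame(activity_rows),
                             overlap_table=overlap_table, metadata=metadata)
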