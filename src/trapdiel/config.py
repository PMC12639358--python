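"""Run configuration for the diel-activity pipeline.

All tunable constants of the analysis live in :class:`AnalysisConfig` so a
whole run is reproducible from one YAML/JSON file plus a seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants governing every stage of the analysis.

    Parameters
    ----------
    independence_interval_min : int
        Minimum spacing, in minutes, between consecutive retained records of
        the same species at the same site (temporal independence rule).
    abundance_threshold : int
        A species is "abundant" — analysed on its own and classified from its
        own data — when its independent detections exceed this count.
    bootstrap_reps : int
        Replicates for the electivity bootstrap and the smoothed bootstrap
        behind overlap confidence intervals.
    accumulation_permutations : int
        Random orderings of sampling units for the species accumulation curve.
    delta_n_threshold : int
        Overlap estimator switch: the grid-based estimator (Dhat1) is used
        when the smaller sample is strictly below this size, the point-based
        estimator (Dhat4) otherwise.
    ci_level : float
        Two-sided confidence level for bootstrap intervals.
    percentile_breaks : tuple of float
        Percentiles of the within-study overlap distribution separating
        low / moderate / high overlap.
    activity_class_breaks : tuple of float
        Daylight-proportion cut points separating nocturnal, mostly
        nocturnal, cathemeral, mostly diurnal and diurnal.
    kde_grid_size : int
        Number of evaluation points on the 24-h circle for kernel densities.
    kde_adjust_grid, kde_adjust_point : float
        Bandwidth (concentration) multipliers used when the density feeds the
        grid-based and the point-based overlap estimator respectively.
    min_class_n : int
        Smallest per-class sample for which an overlap comparison is
        attempted; units below it are reported as skipped.
    trophic_min_detections : int
        Trophic groups with fewer independent detections are pooled into
        their nearest neighbour (carnivores into omnivores).
    """

    independence_interval_min: int = 60
    abundance_threshold: int = 40
    bootstrap_reps: int = 10_000
    accumulation_permutations: int = 1000
    delta_n_threshold: int = 75
    ci_level: float = 0.95
    percentile_breaks: tuple[float, float] = (50.0, 75.0)
    rng_seed: int = 0
    activity_class_breaks: tuple[float, float, float, float] = (0.10, 0.30, 0.70, 0.90)
    kde_grid_size: int = 128
    kde_adjust_grid: float = 0.8
    kde_adjust_point: float = 1.0
    min_class_n: int = 8
    trophic_min_detections: int = 40

    def __post_init__(self) -> None:
        if self.independence_interval_min <= 0:
            raise ValueError("independence_interval_min must be positive")
        for name in ("abundance_threshold", "bootstrap_reps",
                     "accumulation_permutations", "delta_n_threshold",
                     "kde_grid_size", "min_class_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        b = self.percentile_breaks
        if not (0 < b[0] < b[1] < 100):
            raise ValueError("percentile_breaks must be strictly increasing in (0, 100)")
        a = self.activity_class_breaks
        if not all(0 < x < 1 for x in a) or any(a[i] >= a[i + 1] for i in range(3)):
            raise ValueError("activity_class_breaks must be strictly increasing in (0, 1)")

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["percentile_breaks"] = list(self.percentile_breaks)
        d["activity_class_breaks"] = list(self.activity_class_breaks)
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("percentile_breaks", "activity_class_breaks"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return AnalysisConfig.from_dict(data)
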