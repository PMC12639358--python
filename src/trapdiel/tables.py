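"""Packaged summary tables from the published survey, with arithmetic helpers.

Two fixtures transcribe the study's printed per-species activity summary and
its tourism-overlap comparison: independent detection counts, Jacobs D per
time band, Watson U² flags, activity/diet labels, and per-unit overlap
coefficients with confidence intervals.  The raw detections behind them were
never deposited, so these tables are inputs for cross-checks, not outputs
the package can recompute.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

__all__ = ["load_activity_summary", "load_tourism_overlap",
           "abundant_detection_sums", "independent_detection_range"]


def _packaged(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("trapdiel.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_activity_summary() -> pd.DataFrame:
    """Per-species detections, band electivity and activity/diet labels."""
    return _packaged("activity_summary_kmwr.csv")


def load_tourism_overlap() -> pd.DataFrame:
    """Per-unit detections by tourist class, overlap coefficient and test."""
    return _packaged("tourism_overlap_kmwr.csv")


def abundant_detection_sums(overlap: pd.DataFrame | None = None) -> tuple[int, int]:
    """Summed (tourist-present, tourist-absent) detections of the species rows."""
    df = load_tourism_overlap() if overlap is None else overlap
    sp = df[df["kind"] == "species"]
    return int(sp["n_present"].sum()), int(sp["n_absent"].sum())


def independent_detection_range(activity: pd.DataFrame | None = None,
                                abundant_only: bool = True) -> tuple[int, int]:
    """(min, max) independent detections; default over the abundant species."""
    df = load_activity_summary() if activity is None else activity
    if abundant_only:
        df = df[df["d_day"].notna()]
    col = df["independent_detections"]
    return int(col.min()), int(col.max())
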