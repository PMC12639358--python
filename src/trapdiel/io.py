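"""CSV readers and writers for detections, traits, calendars and results."""
from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .records import DetectionRecord, TouristCalendar, TraitTable

__all__ = [
    "read_detections", "write_detections", "read_traits", "read_calendar",
    "write_results",
]

_DETECTION_COLUMNS = ("site_id", "species", "date", "time", "n_individuals", "notes")


def read_detections(path: str | Path,
                    schema: Mapping[str, str] | None = None,
                    ) -> list[DetectionRecord]:
    """Read a detections CSV into sorted :class:`DetectionRecord` objects.

    Expected columns: site_id, species, date (YYYY-MM-DD), time (HH:MM),
    n_individuals, notes; ``schema`` maps these canonical names to the file's
    actual column names.  Rows are sorted by (site, species, timestamp); no
    rows are dropped (deduplication is the independence filter's job, not
    the reader's).
    """
    schema = dict(schema or {})
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    colmap = {canon: schema.get(canon, canon) for canon in _DETECTION_COLUMNS}
    unknown = set(schema) - set(_DETECTION_COLUMNS)
    if unknown:
        raise ValueError(f"schema maps unknown columns: {sorted(unknown)}")
    for canon in ("site_id", "species", "date", "time"):
        if colmap[canon] not in df.columns:
            raise ValueError(f"detections file missing column {colmap[canon]!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        raw_date = row[colmap["date"]]
        raw_time = row[colmap["time"]]
        try:
            stamp = dt.datetime.fromisoformat(f"{raw_date}T{raw_time}")
        except ValueError as exc:
            raise ValueError(
                f"row {i}: cannot parse timestamp {raw_date!r} {raw_time!r}"
            ) from exc
        n_col = colmap["n_individuals"]
        n = int(row[n_col]) if n_col in row and row[n_col] != "" else 1
        notes = row.get(colmap["notes"], "") or ""
        records.append(DetectionRecord(site_id=row[colmap["site_id"]],
                                       species=row[colmap["species"]],
                                       timestamp=stamp, n_individuals=n,
                                       notes=notes))
    records.sort(key=lambda r: (r.site_id, r.species, r.timestamp))
    return records


def write_detections(records: Sequence[DetectionRecord], path: str | Path) -> None:
    """Write detections in the CSV dialect :func:`read_detections` consumes."""
    rows = [{"site_id": r.site_id, "species": r.species,
             "date": r.timestamp.date().isoformat(),
             "time": r.timestamp.strftime("%H:%M"),
             "n_individuals": r.n_individuals, "notes": r.notes}
            for r in records]
    pd.DataFrame(rows, columns=list(_DETECTION_COLUMNS)).to_csv(path, index=False)


def read_traits(path: str | Path) -> TraitTable:
    """Trait CSV with columns species, activity_cycle, diet."""
    df = pd.read_csv(path)
    required = {"species", "activity_cycle", "diet"}
    if not required <= set(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    return TraitTable(
        activity={r.species: str(r.activity_cycle).lower() for r in df.itertuples()},
        diet={r.species: str(r.diet).lower() for r in df.itertuples()},
    )


def read_calendar(path: str | Path) -> TouristCalendar:
    """Tourist calendar CSV with columns date, tourists_present (0/1)."""
    df = pd.read_csv(path)
    required = {"date", "tourists_present"}
    if not required <= set(df.columns):
        raise ValueError(f"calendar must have columns {sorted(required)}")
    presence = {dt.date.fromisoformat(str(r.date)): bool(int(r.tourists_present))
                for r in df.itertuples()}
    return TouristCalendar(presence=presence)


def write_results(tables: Mapping[str, pd.DataFrame], path: str | Path,
                  fmt: str = "csv", config: AnalysisConfig | None = None,
                  seed: int | None = None) -> list[Path]:
    """Write named result tables with run metadata.

    ``fmt="csv"`` writes one ``<name>.csv`` per table (floats at 6 decimals,
    deterministic column order) plus a ``manifest.json``; ``fmt="json"``
    writes a single JSON file with the metadata and all tables inline.
    """
    path = Path(path)
    meta = {"seed": seed,
            "config_hash": config.config_hash() if config else None,
            "config": config.to_dict() if config else None}
    written: list[Path] = []

    def _round(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(6)
        return out

    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            target = path / f"{name}.csv"
            _round(df).to_csv(target, index=False, float_format="%.6f")
            written.append(target)
        manifest = path / "manifest.json"
        manifest.write_text(json.dumps(meta, indent=2, sort_keys=True))
        written.append(manifest)
    elif fmt == "json":
        payload = dict(meta)
        payload["tables"] = {
            name: json.loads(_round(df).to_json(orient="records"))
            for name, df in tables.items()}
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written
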