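"""Readers and writers for time-course CSVs, dose–effect tables and reports.

Long-format time-course CSV columns: animal_id, group, dose_a, dose_b,
time_min, flinches.  Dose–effect table CSV columns: dose, effect_pct
(optionally se, n).  All files are UTF-8, comma-separated, header required.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DoseEffectRow,
    FlinchTimeCourse,
    RunConfig,
    TreatmentGroup,
    ValidationError,
)

TIMECOURSE_COLUMNS = ["animal_id", "group", "dose_a", "dose_b", "time_min", "flinches"]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def read_timecourses(
    path, vehicle_label: str | None = None
) -> list[TreatmentGroup]:
    """Read a long-format time-course CSV into treatment groups.

    Rows are grouped by (group, animal_id) and sorted by time within each
    animal.  The vehicle arm is identified by ``vehicle_label`` or, when
    omitted, by a group label equal to "vehicle" (case-insensitive) — never
    inferred from zero doses alone, since control arms of mechanism
    experiments may also carry dose 0.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    if (df["flinches"] < 0).any():
        raise ValidationError("negative flinch count in input")
    dup = df.duplicated(subset=["group", "animal_id", "time_min"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate observation for animal {first['animal_id']!r} "
            f"at t={first['time_min']}"
        )

    groups: list[TreatmentGroup] = []
    for label, gdf in df.groupby("group", sort=False):
        members = []
        for animal, adf in gdf.groupby("animal_id", sort=False):
            adf = adf.sort_values("time_min")
            members.append(
                FlinchTimeCourse(
                    animal_id=str(animal),
                    group_label=str(label),
                    dose_a=float(adf["dose_a"].iloc[0]),
                    dose_b=float(adf["dose_b"].iloc[0]),
                    times=tuple(adf["time_min"]),
                    counts=tuple(adf["flinches"]),
                )
            )
        is_vehicle = (
            str(label) == vehicle_label
            if vehicle_label is not None
            else str(label).lower() == "vehicle"
        )
        groups.append(
            TreatmentGroup(label=str(label), members=tuple(members), is_vehicle=is_vehicle)
        )
    return groups


def write_timecourses(groups: list[TreatmentGroup], path) -> None:
    """Write treatment groups back to the long-format CSV."""
    records = [
        {
            "animal_id": tc.animal_id,
            "group": g.label,
            "dose_a": tc.dose_a,
            "dose_b": tc.dose_b,
            "time_min": t,
            "flinches": c,
        }
        for g in groups
        for tc in g.members
        for t, c in zip(tc.times, tc.counts)
    ]
    pd.DataFrame.from_records(records, columns=TIMECOURSE_COLUMNS).to_csv(
        path, index=False
    )


def read_dose_effect_table(path) -> list[DoseEffectRow]:
    """Read a (dose, effect_pct[, se, n]) CSV, sorted by dose."""
    df = pd.read_csv(path)
    missing = [c for c in ("dose", "effect_pct") if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    rows = [
        DoseEffectRow(
            dose=float(r["dose"]),
            effect_pct=float(r["effect_pct"]),
            se=float(r["se"]) if "se" in df.columns and pd.notna(r.get("se")) else None,
            n=int(r["n"]) if "n" in df.columns and pd.notna(r.get("n")) else None,
        )
        for _, r in df.iterrows()
    ]
    return sorted(rows, key=lambda r: r.dose)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (missing keys take defaults)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, out_dir) -> dict[str, Path]:
    """Write the analysis report bundle under ``out_dir``.

    ``results`` must contain "interaction" (an InteractionResult); it may
    also carry "summaries" (list of AntinociceptionSummary or dicts),
    "fits", and "isobologram" (coordinate dicts).  Written files:

    - results.json — every estimate at full precision
    - summaries.csv — dose/effect table, doses and percentages to 2 dp
    - isobologram.csv — additivity-line and point coordinates, 2 dp

    Returns the mapping of artifact name to path.
    """
    if not results or "interaction" not in results or results["interaction"] is None:
        raise ValueError("no analysis results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = out / "results.json"
    with open(paths["json"], "w", encoding="utf-8") as fh:
        json.dump(_to_jsonable(results), fh, indent=2, sort_keys=True)

    summaries = results.get("summaries")
    if summaries:
        rows = [_to_jsonable(s) for s in summaries]
        df = pd.DataFrame(rows)
        for col in df.columns:
            if df[col].dtype.kind == "f":
                df[col] = df[col].round(2)
        paths["summaries"] = out / "summaries.csv"
        df.to_csv(paths["summaries"], index=False)

    coords = results.get("isobologram")
    if coords:
        df = pd.DataFrame(coords).round(2)
        paths["isobologram"] = out / "isobologram.csv"
        df.to_csv(paths["isobologram"], index=False)

    design = results.get("design")
    if design is not None:
        df = pd.DataFrame(
            design.levels, columns=["dose_a_mg_kg", "dose_b_mg_kg", "total_mg_kg"]
        ).round(2)
        paths["design"] = out / "design_levels.csv"
        df.to_csv(paths["design"], index=False)
    return paths
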