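"""CSV readers and writers for grid records, state records and reports.

Grid CSVs are one row per cell.  Column headers are adapted through a
column-mapping dict (logical field name -> CSV header), so externally
produced tables can be read without renaming columns.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .analysis import CVResult, ScenarioTable, SensitivityReport
from .model import OBSERVED_NODES, GridRecord, StateRecord

__all__ = [
    "DEFAULT_COLUMN_MAPPING",
    "read_grid_csv",
    "write_grid_csv",
    "read_state_records_csv",
    "write_state_records_csv",
    "write_scenario_csv",
    "write_sensitivity_csv",
    "write_cv_csv",
    "write_map_states_csv",
]

#: logical GridRecord field -> default CSV column header
DEFAULT_COLUMN_MAPPING: dict[str, str] = {
    "cell_id": "cell_id",
    "landscape_type": "landscape_type",
    "lulc_class": "lulc_class",
    "slope": "slope_deg",
    "field_capacity": "field_capacity_mm",
    "nutrient_availability": "nutrient_availability_kmolc_ha",
    "soil_texture": "soil_texture",
    "wind_erosion": "wind_erosion",
    "water_erosion": "water_erosion",
    "nitrate_leaching": "nitrate_leaching",
    "nitrogen_surplus": "nitrogen_surplus_kgN_ha",
    "x": "x",
    "y": "y",
}

_REQUIRED = [f for f in DEFAULT_COLUMN_MAPPING if f not in ("x", "y")]
_FLOAT_FIELDS = ("slope", "field_capacity", "nutrient_availability", "nitrogen_surplus")


def read_grid_csv(
    path, mapping: Mapping[str, str] | None = None
) -> list[GridRecord]:
    """Read grid records; errors name the missing column or the bad row."""
    mapping = {**DEFAULT_COLUMN_MAPPING, **(mapping or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [
        f"{field!r} (column {mapping[field]!r})"
        for field in _REQUIRED
        if mapping[field] not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        kwargs = {}
        try:
            for field in _REQUIRED:
                raw = row[mapping[field]]
                if field in _FLOAT_FIELDS:
                    kwargs[field] = float(raw)
                elif field == "lulc_class":
                    kwargs[field] = int(raw)
                elif field == "cell_id":
                    kwargs[field] = raw
                else:
                    kwargs[field] = str(raw)
            for field in ("x", "y"):
                col = mapping.get(field)
                if col and col in df.columns:
                    kwargs[field] = float(row[col])
            records.append(GridRecord(**kwargs))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, data row {i + 1}: {exc}") from exc
    return records


def write_grid_csv(
    records: Sequence[GridRecord], path, mapping: Mapping[str, str] | None = None
) -> None:
    mapping = {**DEFAULT_COLUMN_MAPPING, **(mapping or {})}
    fields = list(DEFAULT_COLUMN_MAPPING)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([mapping[f] for f in fields])
        for rec in records:
            writer.writerow([getattr(rec, f) for f in fields])


def write_state_records_csv(records: Sequence[StateRecord], path) -> None:
    cols = list(OBSERVED_NODES)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            writer.writerow([rec[c] for c in cols])


def read_state_records_csv(path) -> list[StateRecord]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return [dict(zip(df.columns, map(str, row))) for row in df.itertuples(index=False)]


def write_scenario_csv(table: ScenarioTable, path) -> None:
    """One row per (scenario, node, state)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scenario", "node", "state", "probability"])
        for label, _ in table.scenarios:
            for node in table.query:
                post = table.posteriors[label][node]
                for state, p in post.as_dict().items():
                    writer.writerow([label, node, state, repr(p)])


def write_sensitivity_csv(report: SensitivityReport, path) -> None:
    """One row per CPT parameter; derivative columns per target state."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        deriv_cols = [f"d_P_{s}" for s in report.target_states]
        writer.writerow(["node", "parent_combo", "child_state", "theta", *deriv_cols, "max_abs"])
        for e in report.entries:
            writer.writerow(
                [
                    e.node,
                    "|".join(e.parent_combo),
                    e.child_state,
                    repr(e.theta),
                    *[repr(float(d)) for d in e.derivatives],
                    repr(float(max(abs(e.derivatives)))),
                ]
            )


def write_cv_csv(result: CVResult, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fold", "size", "accuracy", "mean_logloss"])
        for i, (size, acc, ll) in enumerate(
            zip(result.fold_sizes, result.fold_accuracy, result.fold_logloss)
        ):
            writer.writerow([i, size, repr(acc), repr(ll)])
        writer.writerow(["mean", sum(result.fold_sizes), repr(result.accuracy), repr(result.logloss)])


def write_map_states_csv(
    rows: Sequence[Mapping[str, object]], nodes: Sequence[str], path
) -> None:
    """Per-cell MAP-state table with coordinates (renderable by any GIS)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "x", "y", *nodes])
        for row in rows:
            writer.writerow([row["cell_id"], row["x"], row["y"], *[row[n] for n in nodes]])
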