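"""Readers and writers for the pipeline's interchange formats.

All tables are UTF-8 CSV with header rows, dates ISO-8601, and NA
encoded as the empty string.  Two annotation dialects are supported: the
plain per-line CSV the pipeline itself writes, and a Zooniverse-style
classification export (one row per classification, drawn lines carried
in a JSON ``annotations`` column) so a real platform download can be fed
straight into the cleaning stage.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    LINE_COLUMNS,
    ChangePointTruth,
    ConsensusParams,
    FieldSpec,
    VolunteerModel,
)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, na_rep="")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lines(lines: pd.DataFrame, path) -> None:
    lines.to_csv(path, index=False, na_rep="")


def read_lines(path) -> pd.DataFrame:
    lines = pd.read_csv(path)
    missing = set(LINE_COLUMNS) - set(lines.columns)
    if missing:
        raise ValueError(f"line table missing columns: {sorted(missing)}")
    lines["attempt_time"] = pd.to_datetime(lines["attempt_time"])
    return lines[LINE_COLUMNS]


def write_truths(truths: Sequence[ChangePointTruth], path) -> None:
    rows = [
        dict(
            series_id=t.series_id,
            date=t.date.date().isoformat(),
            kind=t.kind.value,
            magnitude=t.magnitude,
            gap_days=t.gap_days,
            field_name=t.field_name or "",
            x_px="" if t.x_px is None else t.x_px,
        )
        for t in truths
    ]
    pd.DataFrame(
        rows,
        columns=["series_id", "date", "kind", "magnitude", "gap_days",
                 "field_name", "x_px"],
    ).to_csv(path, index=False)


def read_truths(path) -> list[ChangePointTruth]:
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        out.append(
            ChangePointTruth(
                series_id=str(row["series_id"]),
                date=pd.Timestamp(row["date"]),
                kind=row["kind"],
                magnitude=float(row["magnitude"]),
                gap_days=int(row["gap_days"]),
                field_name=(str(row["field_name"])
                            if isinstance(row["field_name"], str) and row["field_name"]
                            else None),
                x_px=None if pd.isna(row["x_px"]) else float(row["x_px"]),
            )
        )
    return out


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False, na_rep="")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Zooniverse-style classification export

#: drawing-tool index -> line colour in the project's workflow
TOOL_COLOURS = {0: "green", 1: "yellow"}


def read_zooniverse_export(path) -> pd.DataFrame:
    """Parse a classification export into the per-line table.

    Expected columns (extra columns are tolerated): ``classification_id``,
    ``user_name`` (or ``user_id``), ``created_at``, ``subject_ids``, and
    ``annotations`` — a JSON list of tasks whose ``value`` holds the drawn
    lines as objects with an ``x`` position and either a ``tool`` index
    (0 = green / clear, 1 = yellow / uncertain) or a ``tool_label``
    containing "green"/"yellow"/"uncertain".
    """
    raw = pd.read_csv(path)
    person_col = "user_name" if "user_name" in raw.columns else "user_id"
    rows = []
    for _, row in raw.iterrows():
        try:
            tasks = json.loads(row["annotations"])
        except (TypeError, json.JSONDecodeError) as exc:
            raise ValueError(
                f"classification {row.get('classification_id')}: bad annotations JSON"
            ) from exc
        for task in tasks:
            for line in task.get("value") or []:
                if "x" not in line:
                    continue
                colour = _line_colour(line)
                rows.append(
                    dict(
                        image_id=str(row["subject_ids"]),
                        person_id=str(row[person_col]),
                        classification_id=row["classification_id"],
                        attempt_time=pd.Timestamp(row["created_at"]),
                        x_px=float(line["x"]),
                        colour=colour,
                    )
                )
    return pd.DataFrame(rows, columns=LINE_COLUMNS)


def _line_colour(line: dict) -> str:
    label = str(line.get("tool_label", "")).lower()
    if "yellow" in label or "uncertain" in label:
        return "yellow"
    if "green" in label or "clear" in label:
        return "green"
    return TOOL_COLOURS.get(int(line.get("tool", 0)), "green")


# ---------------------------------------------------------------------------
# YAML configuration

def fieldspecs_from_yaml(payload) -> list[FieldSpec]:
    """Field specifications from a parsed YAML list of mappings."""
    out = []
    for item in payload:
        out.append(
            FieldSpec(
                name=item["name"],
                field_type=item["type"],
                has_time_element=bool(item.get("has_time_element", False)),
                subcategories=tuple(item["subcategories"])
                if item.get("subcategories")
                else None,
            )
        )
    return out


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def dump_yaml(payload: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def volunteer_model_from_yaml(payload: dict) -> VolunteerModel:
    return VolunteerModel(**payload)


def consensus_params_from_yaml(payload: dict) -> ConsensusParams:
    return ConsensusParams(**payload)
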