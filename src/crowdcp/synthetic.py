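"""Synthetic record extracts and simulated annotation behaviour.

The generator produces typed record tables with known injected temporal
artefacts of the five kinds volunteers were trained on — changes in
level, trend, (vertical) variability, presence/absence of data points,
and isolated outliers — plus simulated volunteer and expert vertical-line
annotations over rendered plot coordinates.  Together these make every
downstream stage (aggregation, cleaning, consensus, evaluation) testable
end to end without access to real clinical data.

Magnitudes are expressed in baseline standard deviations of the affected
numeric field; a trend artefact adds magnitude * sd per 30 days.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .render import PlotCoordinates, date_to_px
from .types import (
    LINE_COLUMNS,
    ChangeKind,
    ChangePointTruth,
    FieldSpec,
    FieldType,
    VolunteerModel,
)

BASELINE_MEAN = 50.0
BASELINE_SD = 10.0


class ConfigurationError(ValueError):
    pass


def generate_extract(
    fields: Sequence[FieldSpec],
    date_span: tuple,
    truths: Sequence[ChangePointTruth] = (),
    seed: int = 0,
    *,
    records_per_day: float = 50.0,
    missing_rate: float = 0.05,
) -> pd.DataFrame:
    """Generate a record extract whose aggregates show the given truths.

    Records arrive at Poisson(``records_per_day``) per day across
    ``date_span``.  Baselines per field type: Numeric ~ N(50, 10);
    Categorical drawn from the declared subcategories (or A/B/C);
    Datetime = record date plus a random time of day (sometimes exactly
    midnight); UniqueIdentifier = sequential zero-padded ids; Freetext =
    short random words.  Non-timepoint fields are missing (empty) at
    ``missing_rate``.

    Artefacts are applied to the first Numeric field unless a truth names
    a field: ``level`` shifts the mean from its date onward; ``trend``
    adds a slope break; ``variability`` scales the spread; ``presence``
    removes all records over ``gap_days``; ``outlier`` shifts a single
    day.
    """
    tp_fields = [f for f in fields if f.field_type is FieldType.TIMEPOINT]
    if len(tp_fields) != 1:
        raise ConfigurationError(
            f"spec must contain exactly one timepoint field, found {len(tp_fields)}"
        )
    start, end = pd.Timestamp(date_span[0]), pd.Timestamp(date_span[1])
    if end < start:
        raise ConfigurationError("empty date span")
    rng = np.random.default_rng(seed)
    days = pd.date_range(start, end, freq="D")
    for t in truths:
        if not (start <= t.date <= end):
            raise ConfigurationError(f"truth at {t.date} outside the date span")

    counts = rng.poisson(records_per_day, size=len(days))
    counts = np.maximum(counts, 1)  # keep the daily index gap-free
    for t in truths:
        if t.kind is ChangeKind.PRESENCE:
            gap = (days >= t.date) & (days < t.date + pd.Timedelta(days=t.gap_days))
            counts[gap] = 0

    record_days = pd.DatetimeIndex(np.repeat(days, counts))
    n = len(record_days)
    if n == 0:
        raise ConfigurationError("all timepoints removed by presence artefacts")
    data: dict[str, object] = {}
    tp_name = tp_fields[0].name

    numeric_fields = [f for f in fields if f.field_type is FieldType.NUMERIC]
    default_target = numeric_fields[0].name if numeric_fields else None

    for f in fields:
        if f.field_type is FieldType.TIMEPOINT:
            if f.has_time_element:
                secs = rng.integers(0, 86_400, size=n)
                data[f.name] = record_days + pd.to_timedelta(secs, unit="s")
            else:
                data[f.name] = record_days
        elif f.field_type is FieldType.NUMERIC:
            vals = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
            vals = _apply_numeric_truths(vals, record_days, truths, f.name,
                                         default_target)
            data[f.name] = vals
        elif f.field_type is FieldType.CATEGORICAL:
            cats = list(f.subcategories) if f.subcategories else ["A", "B", "C"]
            data[f.name] = rng.choice(cats, size=n)
        elif f.field_type is FieldType.DATETIME:
            secs = rng.integers(0, 86_400, size=n)
            at_midnight = rng.random(n) < 0.3
            secs[at_midnight] = 0
            data[f.name] = (record_days + pd.to_timedelta(secs, unit="s")).strftime(
                "%Y-%m-%d %H:%M:%S"
            )
        elif f.field_type is FieldType.UNIQUE_IDENTIFIER:
            data[f.name] = [f"ID{seed % 97:02d}{i:08d}" for i in range(n)]
        elif f.field_type is FieldType.FREETEXT:
            words = np.array(["seen by dr", "follow up", "routine", "urgent", "na"])
            data[f.name] = rng.choice(words, size=n)
    records = pd.DataFrame(data)

    # inject missingness into non-timepoint fields
    for f in fields:
        if f.field_type is FieldType.TIMEPOINT or missing_rate <= 0:
            continue
        mask = rng.random(n) < missing_rate
        col = records[f.name]
        records[f.name] = col.astype(object).where(~mask, np.nan)
    records[tp_name] = pd.to_datetime(records[tp_name])
    return records


def _apply_numeric_truths(vals, record_days, truths, field_name, default_target):
    for t in truths:
        target = t.field_name or default_target
        if target != field_name:
            continue
        after = np.asarray(record_days >= t.date)
        if t.kind is ChangeKind.LEVEL:
            vals = vals + np.where(after, t.magnitude * BASELINE_SD, 0.0)
        elif t.kind is ChangeKind.TREND:
            days_since = (record_days - t.date) / pd.Timedelta(days=1)
            days_since = np.asarray(days_since, dtype=float)
            vals = vals + np.where(after, t.magnitude * BASELINE_SD * days_since / 30.0, 0.0)
        elif t.kind is ChangeKind.VARIABILITY:
            dev = vals - BASELINE_MEAN
            vals = np.where(after, BASELINE_MEAN + dev * (1.0 + t.magnitude), vals)
        elif t.kind is ChangeKind.OUTLIER:
            on_day = after & (np.asarray(record_days) < (t.date + pd.Timedelta(days=1)).to_datetime64())
            vals = vals + np.where(on_day, t.magnitude * BASELINE_SD, 0.0)
    return vals


def truth_pixels(
    truths: Sequence[ChangePointTruth], coords: PlotCoordinates
) -> list[ChangePointTruth]:
    """Attach the x-pixel of each truth's date under the image geometry."""
    out = []
    for t in truths:
        px = t.x_px if t.x_px is not None else date_to_px(t.date, coords)
        out.append(
            ChangePointTruth(
                series_id=t.series_id, date=t.date, kind=t.kind,
                magnitude=t.magnitude, gap_days=t.gap_days,
                field_name=t.field_name, x_px=px,
            )
        )
    return out


def simulate_annotations(
    truths: Sequence[ChangePointTruth],
    coords: PlotCoordinates,
    model: VolunteerModel,
    seed: int = 0,
    *,
    image_id: Optional[str] = None,
    person_prefix: str = "vol",
) -> pd.DataFrame:
    """Simulate volunteer line-drawing on one image.

    Returns an annotation-line table with one row per drawn line.  Each
    classification (attempt) has its own id and timestamp; with
    ``repeat_prob`` a volunteer submits a second, independent attempt, so
    first-attempt filtering downstream is exercised.
    """
    truths = truth_pixels(truths, coords)
    for t in truths:
        if not (coords.left <= t.x_px <= coords.right):
            raise ValueError(f"truth pixel {t.x_px} outside the plot area")
    if image_id is None:
        image_id = truths[0].series_id if truths else "image"
    rng = np.random.default_rng(seed)
    base_time = pd.Timestamp("2021-06-01 12:00:00")
    rows: list[dict] = []
    classification_id = 0
    for v in range(model.n_volunteers):
        person = f"{person_prefix}{v:05d}"
        n_attempts = 1 + int(rng.random() < model.repeat_prob)
        for attempt in range(n_attempts):
            t_attempt = base_time + pd.Timedelta(minutes=v, seconds=30 * attempt)
            classification_id += 1
            for t in truths:
                if rng.random() >= model.detect_prob:
                    continue
                x = t.x_px + (rng.normal(0.0, model.jitter_sd) if model.jitter_sd else 0.0)
                x = float(np.clip(x, coords.left, coords.right))
                colour = "yellow" if rng.random() < model.uncertain_prob else "green"
                rows.append(
                    dict(image_id=image_id, person_id=person,
                         classification_id=classification_id,
                         attempt_time=t_attempt, x_px=x, colour=colour)
                )
            for _ in range(rng.poisson(model.noise_rate)):
                x = float(rng.uniform(coords.left, coords.right))
                colour = "yellow" if rng.random() < model.uncertain_prob else "green"
                rows.append(
                    dict(image_id=image_id, person_id=person,
                         classification_id=classification_id,
                         attempt_time=t_attempt, x_px=x, colour=colour)
                )
    return pd.DataFrame(rows, columns=LINE_COLUMNS)


def simulate_expert(
    truths: Sequence[ChangePointTruth],
    coords: PlotCoordinates,
    seed: int = 0,
    *,
    image_id: Optional[str] = None,
    jitter_sd: float = 0.0,
    uncertain_prob: float = 0.08,
) -> pd.DataFrame:
    """One expert classification per image: a line at (almost) every truth."""
    model = VolunteerModel(
        n_volunteers=1, detect_prob=1.0, jitter_sd=jitter_sd,
        uncertain_prob=uncertain_prob, noise_rate=0.0, repeat_prob=0.0,
    )
    return simulate_annotations(
        truths, coords, model, seed=seed, image_id=image_id, person_prefix="expert"
    )
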