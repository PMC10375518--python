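"""Turn a typed record extract into data-quality time series.

Every field of an extract is summarised per regular time interval (day,
Monday-to-Sunday week, or calendar month) with a set of aggregation
functions determined by its type, covering the intrinsic data-quality
dimensions of completeness (missing values), conformance (values that do
not parse as their declared type), and plausibility (counts, extremes,
central tendency, string lengths, subcategory frequencies).  Two extra
"fields" summarise the extract as a whole (``ALL_DATA``) and the exact
duplicate rows removed before aggregation (``DUPLICATES``).

Intervals with no records take the value 0 for the ``n`` function (no
values present is a real observation) and NA for every other function
(no summary can be computed).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import FieldSpec, FieldType, TimeSeries

GRANULARITY_FREQ = {"day": "D", "week": "W-SUN", "month": "M"}

ALL_DATA = "ALL_DATA"
DUPLICATES = "DUPLICATES"

#: Aggregation-function sets per field type (Table-driven dispatch).
FUNCTIONS_BY_TYPE = {
    FieldType.TIMEPOINT: ["n", "midnight_n", "midnight_perc"],
    FieldType.NUMERIC: [
        "missing_n", "missing_perc", "nonconformant_n", "nonconformant_perc",
        "n", "min", "max", "mean", "median",
    ],
    FieldType.CATEGORICAL: [
        "missing_n", "missing_perc", "n", "distinct", "subcat_n", "subcat_perc",
    ],
    FieldType.DATETIME: [
        "missing_n", "missing_perc", "nonconformant_n", "nonconformant_perc",
        "n", "min", "max", "midnight_n", "midnight_perc",
    ],
    FieldType.UNIQUE_IDENTIFIER: [
        "missing_n", "missing_perc", "n", "minlength", "maxlength", "meanlength",
    ],
    FieldType.FREETEXT: ["missing_n", "missing_perc", "n"],
}

PERCENT_FUNCTIONS = {
    "missing_perc", "nonconformant_perc", "midnight_perc", "subcat_perc",
    "nonzero_perc",
}
FREQUENCY_FUNCTIONS = {
    "n", "missing_n", "nonconformant_n", "midnight_n", "distinct",
    "subcat_n", "sum",
}


class ExtractError(ValueError):
    """Raised when an extract cannot be aggregated (e.g. no valid rows)."""


def _timepoint_field(fields: Sequence[FieldSpec]) -> FieldSpec:
    tps = [f for f in fields if f.field_type is FieldType.TIMEPOINT]
    if len(tps) != 1:
        raise ExtractError(
            f"extract must declare exactly one Timepoint field, found {len(tps)}"
        )
    return tps[0]


def _is_missing(values: pd.Series) -> pd.Series:
    """Missing = NaN/None or an empty / whitespace-only string."""
    miss = values.isna()
    as_str = values.astype("string")
    return miss | as_str.str.strip().fillna("").eq("")


def prepare_extract(
    records: pd.DataFrame, fields: Sequence[FieldSpec]
) -> tuple[pd.DataFrame, pd.Series]:
    """Parse timepoints, drop invalid rows, and deduplicate.

    Rows whose timepoint value is missing or unparseable are excluded
    from all series.  Exact duplicate rows (all columns equal) are then
    removed keeping the first; the timepoints of the removed rows are
    returned so the ``DUPLICATES`` pseudo-field can count them per
    interval.

    Returns
    -------
    (clean, dup_timepoints)
        ``clean`` has its timepoint column parsed to datetime64;
        ``dup_timepoints`` is a Series of the removed rows' timepoints.
    """
    tp = _timepoint_field(fields).name
    if tp not in records.columns:
        raise ExtractError(f"timepoint field {tp!r} not in records")
    parsed = pd.to_datetime(records[tp], errors="coerce", format="mixed")
    valid = records.loc[parsed.notna()].copy()
    if valid.empty:
        raise ExtractError("no rows with a valid timepoint value")
    valid[tp] = parsed.loc[valid.index]
    dup_mask = valid.duplicated(keep="first")
    dup_timepoints = valid.loc[dup_mask, tp]
    clean = valid.loc[~dup_mask].reset_index(drop=True)
    return clean, dup_timepoints.reset_index(drop=True)


def bin_timepoints(dates: pd.Series, granularity: str) -> pd.PeriodIndex:
    """Map each datetime to its interval: day (midnight to midnight),
    week (Monday to Sunday), or calendar month."""
    if granularity not in GRANULARITY_FREQ:
        raise ExtractError(f"unknown granularity {granularity!r}")
    return pd.PeriodIndex(pd.DatetimeIndex(dates), freq=GRANULARITY_FREQ[granularity])


def _full_index(bins: pd.PeriodIndex) -> pd.PeriodIndex:
    return pd.period_range(bins.min(), bins.max(), freq=bins.freq)


def _grouped(values: pd.Series, bins: pd.PeriodIndex, index: pd.PeriodIndex):
    return values.groupby(pd.PeriodIndex(bins, freq=index.freq))


def aggregate_field(
    values: pd.Series,
    bins: pd.PeriodIndex,
    field: FieldSpec,
    *,
    extract_id: str = "extract",
    granularity: str = "day",
    subcategory_limit: int = 20,
    index: Optional[pd.PeriodIndex] = None,
) -> list[TimeSeries]:
    """Aggregate one field's raw values into its set of time series.

    ``values`` and ``bins`` are aligned per record.  ``index`` fixes the
    (gap-free) output interval index; by default it spans the observed
    bins.  Intervals outside any record get ``n`` = 0 and NA elsewhere.
    """
    if field.field_type not in FUNCTIONS_BY_TYPE:
        raise ExtractError(f"unknown field type {field.field_type!r}")
    if index is None:
        index = _full_index(bins)

    missing = _is_missing(values)
    present = values[~missing.to_numpy()]
    grp_all = _grouped(pd.Series(1, index=values.index), bins, index)
    total = grp_all.count().reindex(index)  # NaN on empty intervals
    n = (
        _grouped(pd.Series(1, index=present.index), bins[~missing.to_numpy()], index)
        .count()
        .reindex(index)
        .fillna(0)
        .astype(int)
        if len(present)
        else pd.Series(0, index=index)
    )
    missing_n = (total - n).where(total.notna())

    out: dict[tuple[str, Optional[str]], pd.Series] = {}
    funcs = FUNCTIONS_BY_TYPE[field.field_type]

    if "missing_n" in funcs:
        out[("missing_n", None)] = missing_n
        out[("missing_perc", None)] = 100.0 * missing_n / total
    if "n" in funcs:
        out[("n", None)] = n

    ftype = field.field_type
    present_bins = bins[~missing.to_numpy()]

    if ftype in (FieldType.NUMERIC, FieldType.DATETIME):
        if ftype is FieldType.NUMERIC:
            parsed = pd.to_numeric(present, errors="coerce")
        else:
            parsed = pd.to_datetime(present, errors="coerce", format="mixed")
        conformant = parsed.notna()
        nonconf = (
            _grouped(pd.Series(1, index=present.index[~conformant]),
                     present_bins[~conformant.to_numpy()], index)
            .count()
            .reindex(index)
            .fillna(0)
            if (~conformant).any()
            else pd.Series(0.0, index=index)
        )
        nonconf = nonconf.where(total.notna())
        out[("nonconformant_n", None)] = nonconf
        # denominator = values present (conformant + nonconformant)
        out[("nonconformant_perc", None)] = (100.0 * nonconf / n).where(n > 0)

        good = parsed[conformant]
        good_bins = present_bins[conformant.to_numpy()]
        if ftype is FieldType.DATETIME:
            numeric_good = (
                good.astype("int64") / 86_400_000_000_000.0  # fractional days since epoch
            )
        else:
            numeric_good = good.astype(float)
        if len(numeric_good):
            g = _grouped(numeric_good, good_bins, index)
            stats = {"min": g.min(), "max": g.max()}
            if ftype is FieldType.NUMERIC:
                stats["mean"] = g.mean()
                stats["median"] = g.median()
        else:
            stats = {"min": pd.Series(dtype=float)}
            stats["max"] = stats["min"]
            if ftype is FieldType.NUMERIC:
                stats["mean"] = stats["median"] = stats["min"]
        for label in ("min", "max") + (("mean", "median") if ftype is FieldType.NUMERIC else ()):
            out[(label, None)] = stats[label].reindex(index)

        if ftype is FieldType.DATETIME and field.has_time_element:
            _add_midnight(out, good, good_bins, index)

    if ftype is FieldType.TIMEPOINT and field.has_time_element:
        parsed_tp = pd.to_datetime(present, errors="coerce", format="mixed")
        _add_midnight(out, parsed_tp[parsed_tp.notna()],
                      present_bins[parsed_tp.notna().to_numpy()], index)

    if ftype is FieldType.CATEGORICAL:
        cats = (
            list(field.subcategories)
            if field.subcategories is not None
            else sorted(present.astype(str).unique())
        )
        if len(present):
            distinct = (
                _grouped(present.astype(str), present_bins, index)
                .nunique().reindex(index).fillna(0)
            )
        else:
            distinct = pd.Series(0.0, index=index)
        out[("distinct", None)] = distinct.where(total.notna())
        if len(cats) < subcategory_limit:
            as_str = present.astype(str)
            for cat in cats:
                sel = as_str == cat
                cnt = (
                    _grouped(pd.Series(1, index=present.index[sel.to_numpy()]),
                             present_bins[sel.to_numpy()], index)
                    .count()
                    .reindex(index)
                    .fillna(0)
                    if sel.any()
                    else pd.Series(0.0, index=index)
                )
                cnt = cnt.where(total.notna())
                out[("subcat_n", cat)] = cnt
                out[("subcat_perc", cat)] = (100.0 * cnt / n).where(n > 0)

    if ftype is FieldType.UNIQUE_IDENTIFIER:
        lengths = present.astype(str).str.len().astype(float)
        if len(lengths):
            g = _grouped(lengths, present_bins, index)
            out[("minlength", None)] = g.min().reindex(index)
            out[("maxlength", None)] = g.max().reindex(index)
            out[("meanlength", None)] = g.mean().reindex(index)
        else:
            empty = pd.Series(np.nan, index=index)
            out[("minlength", None)] = empty
            out[("maxlength", None)] = empty
            out[("meanlength", None)] = empty

    return [
        TimeSeries(
            extract_id=extract_id,
            field_name=field.name,
            function_label=label,
            granularity=granularity,
            subcategory=subcat,
            points=pts.astype(float),
        )
        for (label, subcat), pts in out.items()
    ]


def _add_midnight(out, good: pd.Series, good_bins: pd.PeriodIndex,
                  index: pd.PeriodIndex) -> None:
    """midnight_n counts values whose time-of-day is exactly 00:00:00."""
    if len(good):
        is_mid = good.dt.normalize() == good
        parse_n = (
            _grouped(pd.Series(1, index=good.index), good_bins, index)
            .count().reindex(index)
        )
        mid_n = (
            _grouped(pd.Series(1, index=good.index[is_mid.to_numpy()]),
                     good_bins[is_mid.to_numpy()], index)
            .count().reindex(index).fillna(0)
        )
        mid_n = mid_n.where(parse_n.notna())
        out[("midnight_n", None)] = mid_n
        out[("midnight_perc", None)] = (100.0 * mid_n / parse_n).where(parse_n > 0)
    else:
        out[("midnight_n", None)] = pd.Series(np.nan, index=index)
        out[("midnight_perc", None)] = pd.Series(np.nan, index=index)


def _aggregate_extract_level(
    records: pd.DataFrame,
    fields: Sequence[FieldSpec],
    bins: pd.PeriodIndex,
    dup_bins: pd.PeriodIndex,
    index: pd.PeriodIndex,
    extract_id: str,
    granularity: str,
) -> list[TimeSeries]:
    """ALL_DATA (values pooled over all non-timepoint fields) and
    DUPLICATES (exact duplicate rows removed) pseudo-field series."""
    tp_name = _timepoint_field(fields).name
    data_fields = [f for f in fields if f.name != tp_name]

    grp_rows = _grouped(pd.Series(1, index=records.index), bins, index)
    rows = grp_rows.count().reindex(index)

    miss_total = pd.Series(0.0, index=index)
    conf_nonconf = pd.Series(0.0, index=index)
    conf_denom = pd.Series(0.0, index=index)
    n_total = pd.Series(0.0, index=index)
    for f in data_fields:
        vals = records[f.name]
        missing = _is_missing(vals)
        miss_cnt = (
            _grouped(missing.astype(float), bins, index).sum().reindex(index).fillna(0)
        )
        present_cnt = (
            _grouped((~missing).astype(float), bins, index).sum().reindex(index).fillna(0)
        )
        miss_total += miss_cnt
        n_total += present_cnt
        if f.field_type in (FieldType.NUMERIC, FieldType.DATETIME):
            present = vals[~missing.to_numpy()]
            if f.field_type is FieldType.NUMERIC:
                bad = pd.to_numeric(present, errors="coerce").isna()
            else:
                bad = pd.to_datetime(present, errors="coerce", format="mixed").isna()
            pb = bins[~missing.to_numpy()]
            if bad.any():
                conf_nonconf += (
                    _grouped(pd.Series(1.0, index=present.index[bad.to_numpy()]),
                             pb[bad.to_numpy()], index)
                    .sum().reindex(index).fillna(0)
                )
            conf_denom += present_cnt

    has_rows = rows.notna()
    fields_total = miss_total + n_total
    series = [
        ("missing_n", miss_total.where(has_rows)),
        ("missing_perc", (100.0 * miss_total / fields_total).where(fields_total > 0)),
        ("nonconformant_n", conf_nonconf.where(has_rows)),
        ("nonconformant_perc",
         (100.0 * conf_nonconf / conf_denom).where(conf_denom > 0)),
        ("n", n_total.fillna(0)),
    ]
    out = [
        TimeSeries(extract_id, ALL_DATA, label, granularity, pts.astype(float))
        for label, pts in series
    ]

    if len(dup_bins):
        dups = (
            _grouped(pd.Series(1.0, index=range(len(dup_bins))), dup_bins, index)
            .sum().reindex(index).fillna(0)
        )
    else:
        dups = pd.Series(0.0, index=index)
    dups = dups.where(has_rows)
    denom = rows + dups.fillna(0)
    out.append(TimeSeries(extract_id, DUPLICATES, "sum", granularity, dups.astype(float)))
    out.append(
        TimeSeries(
            extract_id, DUPLICATES, "nonzero_perc", granularity,
            (100.0 * dups / denom).where(denom > 0).astype(float),
        )
    )
    return out


def aggregate_extract(
    records: pd.DataFrame,
    fields: Sequence[FieldSpec],
    *,
    extract_id: str = "extract",
    granularities: Iterable[str] = ("day", "week", "month"),
    subcategory_limit: int = 20,
) -> list[TimeSeries]:
    """Full pipeline: prepare, bin at each granularity, aggregate every
    field plus the ALL_DATA and DUPLICATES pseudo-fields."""
    clean, dup_tp = prepare_extract(records, fields)
    tp_name = _timepoint_field(fields).name
    out: list[TimeSeries] = []
    for gran in granularities:
        bins = bin_timepoints(clean[tp_name], gran)
        dup_bins = bin_timepoints(dup_tp, gran) if len(dup_tp) else pd.PeriodIndex(
            [], freq=GRANULARITY_FREQ[gran]
        )
        index = _full_index(bins)
        for f in fields:
            out.extend(
                aggregate_field(
                    clean[f.name], bins, f,
                    extract_id=extract_id, granularity=gran,
                    subcategory_limit=subcategory_limit, index=index,
                )
            )
        out.extend(
            _aggregate_extract_level(
                clean, fields, bins, dup_bins, index, extract_id, gran
            )
        )
    return out


def series_to_frame(series: Iterable[TimeSeries]) -> pd.DataFrame:
    """Tidy long format: one row per (series, timepoint); NA kept as NaN."""
    rows = []
    for ts in series:
        for period, value in ts.points.items():
            rows.append(
                {
                    "extract_id": ts.extract_id,
                    "field": ts.field_name,
                    "function": ts.function_label,
                    "subcategory": ts.subcategory,
                    "granularity": ts.granularity,
                    "timepoint": period.start_time.date().isoformat(),
                    "value": value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "extract_id", "field", "function", "subcategory",
            "granularity", "timepoint", "value",
        ],
    )
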