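"""Aggregation of typed record extracts into data-quality series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crowdcp import FieldSpec, generate_extract
from crowdcp.aggregate import (
    ExtractError,
    aggregate_extract,
    aggregate_field,
    bin_timepoints,
    prepare_extract,
    series_to_frame,
)


def by_key(series, field, function, subcategory=None):
    for s in series:
        if (s.field_name, s.function_label, s.subcategory) == (
            field, function, subcategory
        ):
            return s.points
    raise KeyError((field, function, subcategory))


def build(records, fields, **kwargs):
    return aggregate_extract(pd.DataFrame(records), fields,
                             granularities=kwargs.pop("granularities", ["day"]),
                             **kwargs)


class TestPrepare:
    def test_exact_duplicates_removed_and_counted(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]
        rec = pd.DataFrame(
            {"d": ["2020-01-01"] * 3 + ["2020-01-02"], "v": [1.0, 1.0, 1.0, 2.0]}
        )
        clean, dups = prepare_extract(rec, fields)
        assert len(clean) == 2
        assert len(dups) == 2
        assert (dups.dt.date.astype(str) == "2020-01-01").all()

    def test_invalid_timepoint_rows_excluded_everywhere(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]
        rec = pd.DataFrame({"d": ["2020-01-01", "not a date", None],
                            "v": [1.0, 2.0, 3.0]})
        clean, _ = prepare_extract(rec, fields)
        assert len(clean) == 1
        assert clean["v"].tolist() == [1.0]

    def test_all_rows_invalid_raises(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]
        with pytest.raises(ExtractError):
            prepare_extract(pd.DataFrame({"d": ["??", None], "v": [1, 2]}), fields)

    def test_no_duplicates_gives_zero_sum_series(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]
        series = build(
            {"d": ["2020-01-01", "2020-01-02"], "v": [1.0, 2.0]}, fields
        )
        assert by_key(series, "DUPLICATES", "sum").fillna(-1).eq(0).all()


class TestBinning:
    def test_sunday_maps_to_week_starting_preceding_monday(self):
        bins = bin_timepoints(pd.Series(pd.to_datetime(["2019-06-30"])), "week")
        assert bins[0].start_time == pd.Timestamp("2019-06-24")  # a Monday
        assert bins[0].start_time.day_name() == "Monday"

    def test_month_bin_is_calendar_month(self):
        bins = bin_timepoints(pd.Series(pd.to_datetime(["2019-06-30"])), "month")
        assert bins[0].start_time == pd.Timestamp("2019-06-01")
        assert bins[0].end_time.date() == pd.Timestamp("2019-06-30").date()

    def test_same_day_different_times_share_day_bin(self):
        dates = pd.Series(pd.to_datetime(["2020-03-05 00:10", "2020-03-05 23:59"]))
        bins = bin_timepoints(dates, "day")
        assert bins[0] == bins[1]

    def test_unknown_granularity_rejected(self):
        with pytest.raises(ExtractError):
            bin_timepoints(pd.Series(pd.to_datetime(["2020-01-01"])), "year")


class TestNumericAggregation:
    fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]

    def test_single_day_summary(self):
        series = build(
            {"d": ["2020-01-01"] * 3, "v": [1.0, None, 3.0]}, self.fields
        )
        assert by_key(series, "v", "missing_n").iloc[0] == 1
        assert by_key(series, "v", "missing_perc").iloc[0] == pytest.approx(100 / 3)
        assert by_key(series, "v", "n").iloc[0] == 2
        assert by_key(series, "v", "min").iloc[0] == 1.0
        assert by_key(series, "v", "max").iloc[0] == 3.0
        assert by_key(series, "v", "mean").iloc[0] == 2.0
        assert by_key(series, "v", "median").iloc[0] == 2.0

    def test_nonnumeric_value_is_nonconformant(self):
        series = build(
            {"d": ["2020-01-01", "2020-01-01"], "v": ["abc", "2.5"]}, self.fields
        )
        assert by_key(series, "v", "nonconformant_n").iloc[0] == 1
        assert by_key(series, "v", "nonconformant_perc").iloc[0] == 50.0
        # summaries use the conformant values only
        assert by_key(series, "v", "mean").iloc[0] == 2.5

    def test_empty_interval_n_zero_others_na(self):
        series = build(
            {"d": ["2020-01-01", "2020-01-03"], "v": [1.0, 2.0]}, self.fields
        )
        n = by_key(series, "v", "n")
        mean = by_key(series, "v", "mean")
        missing = by_key(series, "v", "missing_n")
        middle = pd.Period("2020-01-02", freq="D")
        assert n.loc[middle] == 0
        assert np.isnan(mean.loc[middle])
        assert np.isnan(missing.loc[middle])

    def test_median_of_even_count_is_mean_of_central_pair(self):
        series = build(
            {"d": ["2020-01-01"] * 4, "v": [1.0, 2.0, 10.0, 20.0]}, self.fields
        )
        assert by_key(series, "v", "median").iloc[0] == 6.0


class TestCategorical:
    def test_subcategories_suppressed_at_limit(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("c", "Categorical")]
        cats = [f"c{i:02d}" for i in range(21)]
        series = build({"d": ["2020-01-01"] * 21, "c": cats}, fields)
        labels = {(s.field_name, s.function_label) for s in series}
        assert ("c", "distinct") in labels
        assert ("c", "subcat_n") not in labels
        assert ("c", "subcat_perc") not in labels

    def test_configurable_limit_admits_23_categories(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("c", "Categorical")]
        cats = [f"c{i:02d}" for i in range(23)]
        series = build({"d": ["2020-01-01"] * 23, "c": cats}, fields,
                       subcategory_limit=24)
        subcats = [s for s in series if s.function_label == "subcat_n"]
        assert len(subcats) == 23

    def test_subcategory_closure(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("c", "Categorical")]
        rng = np.random.default_rng(11)
        days = rng.choice(pd.date_range("2020-01-01", periods=10).astype(str), 200)
        series = build(
            {"d": days, "c": rng.choice(["a", "b", "c"], 200)}, fields
        )
        n = by_key(series, "c", "n")
        total_sub = sum(by_key(series, "c", "subcat_n", c) for c in "abc")
        pd.testing.assert_series_equal(total_sub, n.astype(float),
                                       check_names=False)
        perc_sum = sum(by_key(series, "c", "subcat_perc", c) for c in "abc")
        assert np.allclose(perc_sum[n > 0], 100.0)


class TestDatetimeAndIdentifier:
    def test_midnight_counts_require_time_element(self):
        f_with = [FieldSpec("d", "Timepoint"),
                  FieldSpec("t", "Datetime", has_time_element=True)]
        f_without = [FieldSpec("d", "Timepoint"), FieldSpec("t", "Datetime")]
        rec = {"d": ["2020-01-01"] * 3,
               "t": ["2020-02-01 00:00:00", "2020-02-01 13:30:00", "bad"]}
        with_mid = build(rec, f_with)
        without_mid = build(rec, f_without)
        assert by_key(with_mid, "t", "midnight_n").iloc[0] == 1
        assert by_key(with_mid, "t", "midnight_perc").iloc[0] == 50.0
        assert by_key(with_mid, "t", "nonconformant_n").iloc[0] == 1
        labels = {s.function_label for s in without_mid if s.field_name == "t"}
        assert "midnight_n" not in labels

    def test_identifier_string_lengths(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("u", "UniqueIdentifier")]
        series = build(
            {"d": ["2020-01-01"] * 2, "u": ["ab", "abcd"]}, fields
        )
        assert by_key(series, "u", "minlength").iloc[0] == 2
        assert by_key(series, "u", "maxlength").iloc[0] == 4
        assert by_key(series, "u", "meanlength").iloc[0] == 3


@pytest.fixture(scope="module")
def generated():
    fields = [
        FieldSpec("spec_date", "Timepoint"),
        FieldSpec("value", "Numeric"),
        FieldSpec("category", "Categorical"),
        FieldSpec("uid", "UniqueIdentifier"),
    ]
    records = generate_extract(
        fields, ("2020-01-01", "2020-03-31"), seed=42, records_per_day=15
    )
    return fields, aggregate_extract(
        records, fields, granularities=["day", "week", "month"]
    )


class TestInvariants:

    def test_conservation_missing_plus_n_is_total(self, generated):
        fields, series = generated
        daily = [s for s in series if s.granularity == "day"]
        total = by_key(daily, "spec_date", "n")
        for name in ("value", "category", "uid"):
            miss = by_key(daily, name, "missing_n")
            n = by_key(daily, name, "n")
            ok = total > 0
            assert np.allclose((miss + n)[ok], total[ok])

    def test_missing_perc_formula(self, generated):
        _, series = generated
        for s in series:
            if s.function_label != "missing_perc":
                continue
            miss = next(
                t for t in series
                if (t.field_name, t.function_label, t.granularity)
                == (s.field_name, "missing_n", s.granularity)
            ).points
            n = next(
                t for t in series
                if (t.field_name, t.function_label, t.granularity)
                == (s.field_name, "n", s.granularity)
            ).points
            denom = miss + n
            expect = 100.0 * miss / denom
            assert np.allclose(s.points[denom > 0], expect[denom > 0])

    def test_weekly_n_sums_daily_n(self, generated):
        _, series = generated
        daily = by_key([s for s in series if s.granularity == "day"], "value", "n")
        weekly = by_key([s for s in series if s.granularity == "week"], "value", "n")
        resummed = daily.groupby(daily.index.asfreq("W-SUN")).sum()
        # edge weeks cover only the days inside the extract's span
        common = weekly.index.intersection(resummed.index)
        assert np.allclose(weekly.loc[common], resummed.loc[common])

    def test_gap_free_regular_index(self, generated):
        _, series = generated
        for s in series:
            idx = s.points.index
            full = pd.period_range(idx.min(), idx.max(), freq=idx.freq)
            assert idx.equals(full)

    def test_percentages_bounded(self, generated):
        _, series = generated
        for s in series:
            if s.function_label.endswith("perc"):
                vals = s.points.dropna()
                assert ((vals >= 0) & (vals <= 100.0 + 1e-9)).all()

    def test_tidy_frame_keeps_na_and_columns(self):
        fields = [FieldSpec("d", "Timepoint"), FieldSpec("v", "Numeric")]
        series = build(
            {"d": ["2020-01-01", "2020-01-03"], "v": [1.0, 2.0]}, fields
        )
        frame = series_to_frame(series)
        assert list(frame.columns) == [
            "extract_id", "field", "function", "subcategory",
            "granularity", "timepoint", "value",
        ]
        gap = frame[(frame["function"] == "mean")
                    & (frame["timepoint"] == "2020-01-02")]
        assert len(gap) == 1 and gap["value"].isna().all()
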