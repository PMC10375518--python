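from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from crowdcp import ChangePointTruth, FieldSpec, PlotCoordinates

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def basic_fields() -> list[FieldSpec]:
    return [
        FieldSpec("spec_date", "Timepoint"),
        FieldSpec("value", "Numeric"),
        FieldSpec("category", "Categorical"),
        FieldSpec("uid", "UniqueIdentifier"),
    ]


@pytest.fixture(scope="session")
def year_coords() -> PlotCoordinates:
    """Daily-granularity geometry covering calendar year 2020."""
    return PlotCoordinates(
        date_min=pd.Timestamp("2020-01-01"),
        date_max=pd.Timestamp("2020-12-31"),
        granularity="day",
    )


@pytest.fixture
def level_truth() -> ChangePointTruth:
    return ChangePointTruth("img", pd.Timestamp("2020-06-01"), "level", magnitude=8.0)


def make_lines(rows) -> pd.DataFrame:
    """Annotation-line table from (image, person, cid, time, x, colour) tuples."""
    return pd.DataFrame(
        rows,
        columns=["image_id", "person_id", "classification_id",
                 "attempt_time", "x_px", "colour"],
    ).assign(attempt_time=lambda d: pd.to_datetime(d["attempt_time"]))
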