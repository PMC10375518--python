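"""Shared domain types.

Tables (record extracts, annotation lines, consensus labels, tidy series)
are carried as :class:`pandas.DataFrame` objects with documented column
schemas; the dataclasses here hold the scalar configuration and result
objects that travel between pipeline stages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


class FieldType(str, enum.Enum):
    """Taxonomy of EHR extract fields, which decides the aggregation set."""

    TIMEPOINT = "Timepoint"
    NUMERIC = "Numeric"
    CATEGORICAL = "Categorical"
    DATETIME = "Datetime"
    UNIQUE_IDENTIFIER = "UniqueIdentifier"
    FREETEXT = "Freetext"


class ChangeKind(str, enum.Enum):
    """The five kinds of abrupt change volunteers were trained to spot."""

    LEVEL = "level"
    TREND = "trend"
    VARIABILITY = "variability"
    PRESENCE = "presence"
    OUTLIER = "outlier"


#: Columns of an annotation-line table (volunteer or expert).
LINE_COLUMNS = [
    "image_id",
    "person_id",
    "classification_id",
    "attempt_time",
    "x_px",
    "colour",
]

#: Columns of a consensus-label table.
LABEL_COLUMNS = ["image_id", "x_px", "n_contributors", "date"]


@dataclass(frozen=True)
class FieldSpec:
    """Declaration of one field of a typed record extract."""

    name: str
    field_type: FieldType
    has_time_element: bool = False
    subcategories: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_type", FieldType(self.field_type))


@dataclass(frozen=True)
class ChangePointTruth:
    """A known injected change point in a synthetic extract.

    ``magnitude`` is expressed in baseline standard deviations of the
    affected field.  ``gap_days`` only applies to ``presence`` truths.
    """

    series_id: str
    date: pd.Timestamp
    kind: ChangeKind
    magnitude: float = 5.0
    gap_days: int = 14
    field_name: Optional[str] = None
    x_px: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ChangeKind(self.kind))
        object.__setattr__(self, "date", pd.Timestamp(self.date))


@dataclass(frozen=True)
class VolunteerModel:
    """Stochastic model of volunteer annotation behaviour.

    Volunteers are i.i.d.: each detects each true change point with
    ``detect_prob``, drawing a vertical line at the true pixel plus
    Gaussian jitter, coloured yellow (uncertain) with ``uncertain_prob``
    and green otherwise; each also draws Poisson(``noise_rate``) spurious
    lines placed uniformly across the plot area, and with ``repeat_prob``
    submits a second, independent classification of the same image.
    """

    n_volunteers: int = 41
    detect_prob: float = 0.8
    jitter_sd: float = 2.0
    uncertain_prob: float = 0.1
    noise_rate: float = 0.3
    repeat_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("detect_prob", "uncertain_prob", "repeat_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if self.n_volunteers < 0:
            raise ValueError("n_volunteers must be >= 0")


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the raw-annotation cleaning rules."""

    min_distance_cutoff_px: float = 7.0
    max_people_per_image: int = 41

    def __post_init__(self) -> None:
        if self.min_distance_cutoff_px <= 0:
            raise ValueError("min_distance_cutoff_px must be > 0")
        if self.max_people_per_image < 1:
            raise ValueError("max_people_per_image must be >= 1")


@dataclass(frozen=True)
class ConsensusParams:
    """Tuning parameters of the consensus-label clustering."""

    include_yellow: bool = False
    min_pts: int = 5
    eps_px: float = 3.0

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.eps_px <= 0:
            raise ValueError("eps_px must be > 0")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled 2x2 confusion counts of the binary-classifier approximation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Point estimates and 95% CIs of the classifier performance metrics.

    Proportions are on the [0, 1] scale; ``mcc`` lies in [-1, 1] and has
    no CI (it is not a binomial proportion).  A metric whose denominator
    is zero is ``None``.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    mcc: float
    ci_95: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TimeSeries:
    """One aggregated data-quality series.

    ``points`` is a pandas Series indexed by a gap-free
    :class:`pandas.PeriodIndex` spanning the extract's date range;
    values may be NaN (except ``n``-type counts, which are 0 on empty
    intervals).
    """

    extract_id: str
    field_name: str
    function_label: str
    granularity: str
    points: pd.Series
    subcategory: Optional[str] = None

    @property
    def key(self) -> str:
        """Stable identifier used as the rendered image id."""
        parts = [self.extract_id, self.field_name, self.function_label]
        if self.subcategory is not None:
            parts.append(str(self.subcategory))
        parts.append(self.granularity)
        return "__".join(str(p).replace("__", "_") for p in parts)
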