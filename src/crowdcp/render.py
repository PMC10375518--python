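"""Fixed-geometry plotting and the pixel <-> date affine mapping.

Every series is rendered to a 1000 x 666 px PNG at 96 dpi with an
identical plot area, so that an x-pixel drawn on any image can be mapped
back to a date with the same affine transform.  Axis scale rules:
frequency (count) functions start at zero and end no earlier than 10;
percentages are always on a 0-100 scale; subcategory count series share
the y-scale of the whole-field count series.

The plot-area width defaults to 952 px, which makes the candidate region
hold exactly 136 seven-pixel intervals — the constant the evaluation
stage uses to estimate true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .aggregate import FREQUENCY_FUNCTIONS, GRANULARITY_FREQ, PERCENT_FUNCTIONS
from .types import TimeSeries

IMAGE_WIDTH_PX = 1000
IMAGE_HEIGHT_PX = 666
DPI = 96

# Plot-area bounds giving a 952 px wide candidate region.
PLOT_LEFT = 24.0
PLOT_RIGHT = 976.0
PLOT_TOP = 20.0
PLOT_BOTTOM = 636.0


@dataclass(frozen=True)
class PlotCoordinates:
    """Geometry of one rendered image plus its date span.

    The x mapping is affine and strictly increasing: ``date_min`` maps to
    ``left`` and ``date_max`` to ``right``.
    """

    date_min: pd.Timestamp
    date_max: pd.Timestamp
    granularity: str = "day"
    image_width_px: int = IMAGE_WIDTH_PX
    image_height_px: int = IMAGE_HEIGHT_PX
    left: float = PLOT_LEFT
    right: float = PLOT_RIGHT
    top: float = PLOT_TOP
    bottom: float = PLOT_BOTTOM

    def __post_init__(self) -> None:
        object.__setattr__(self, "date_min", pd.Timestamp(self.date_min))
        object.__setattr__(self, "date_max", pd.Timestamp(self.date_max))
        if not (0 < self.left < self.right < self.image_width_px):
            raise ValueError("plot area must lie strictly inside the image")
        if not (0 < self.top < self.bottom < self.image_height_px):
            raise ValueError("plot area must lie strictly inside the image")

    @property
    def plot_width_px(self) -> float:
        return self.right - self.left

    @classmethod
    def for_series(cls, series: TimeSeries, **kwargs) -> "PlotCoordinates":
        idx = series.points.index
        return cls(
            date_min=idx[0].start_time,
            date_max=idx[-1].start_time,
            granularity=series.granularity,
            **kwargs,
        )


def date_to_px(date, coords: PlotCoordinates) -> float:
    """Affine map of a date onto the plot area's x range."""
    d = pd.Timestamp(date)
    if d < coords.date_min or d > coords.date_max:
        raise ValueError(f"date {d} outside span [{coords.date_min}, {coords.date_max}]")
    span = (coords.date_max - coords.date_min).value
    if span == 0:
        return (coords.left + coords.right) / 2.0
    frac = (d - coords.date_min).value / span
    return coords.left + frac * coords.plot_width_px


def px_to_date(x_px: float, coords: PlotCoordinates) -> pd.Timestamp:
    """Inverse affine map; fractional pixels give fractional dates."""
    frac = (x_px - coords.left) / coords.plot_width_px
    span = coords.date_max - coords.date_min
    return coords.date_min + frac * span


def px_to_timepoint(x_px: float, coords: PlotCoordinates) -> pd.Timestamp:
    """Convert a pixel back to the start of the nearest timepoint interval."""
    raw = px_to_date(x_px, coords)
    freq = GRANULARITY_FREQ[coords.granularity]
    starts = pd.period_range(coords.date_min, coords.date_max, freq=freq).start_time
    i = int(np.argmin(np.abs((starts - raw).values.astype("int64"))))
    return starts[i]


def y_limits(series: TimeSeries, field_count_max: Optional[float] = None):
    """Axis rules: counts 0..max(10, data max); percentages 0..100;
    subcategory counts share the whole-field count scale; other values free."""
    values = series.points.dropna()
    fn = series.function_label
    if fn in PERCENT_FUNCTIONS:
        return 0.0, 100.0
    if fn in FREQUENCY_FUNCTIONS:
        top = float(values.max()) if len(values) else 0.0
        if fn == "subcat_n" and field_count_max is not None:
            top = max(top, float(field_count_max))
        return 0.0, max(10.0, top)
    if not len(values):
        return 0.0, 1.0
    lo, hi = float(values.min()), float(values.max())
    pad = 0.05 * (hi - lo) or 0.5
    return lo - pad, hi + pad


def render(
    series: TimeSeries,
    path,
    coords: Optional[PlotCoordinates] = None,
    field_count_max: Optional[float] = None,
) -> PlotCoordinates:
    """Render a series as a scatter PNG with the fixed geometry.

    NA values are rendered as absent points (gaps).  No metadata is drawn
    inside the plot area.  Returns the coordinates used, to be written to
    the manifest so annotations can be converted back to dates.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not len(series.points):
        raise ValueError("cannot render an empty series")
    if coords is None:
        coords = PlotCoordinates.for_series(series)

    fig = plt.figure(
        figsize=(coords.image_width_px / DPI, coords.image_height_px / DPI), dpi=DPI
    )
    # axes placed so data coordinates land exactly on the plot-area pixels
    ax = fig.add_axes(
        (
            coords.left / coords.image_width_px,
            (coords.image_height_px - coords.bottom) / coords.image_height_px,
            coords.plot_width_px / coords.image_width_px,
            (coords.bottom - coords.top) / coords.image_height_px,
        )
    )
    x = series.points.index.start_time
    y = series.points.to_numpy(dtype=float)
    ax.scatter(x, y, s=4, color="black")
    ax.set_xlim(coords.date_min, coords.date_max)
    ax.set_ylim(*y_limits(series, field_count_max=field_count_max))
    ax.margins(0)
    ax.tick_params(labelsize=6)
    fig.savefig(path, dpi=DPI)
    plt.close(fig)
    return coords


def manifest_frame(entries: dict[str, PlotCoordinates]) -> pd.DataFrame:
    """Image id -> geometry table, enough to invert pixel positions."""
    rows = []
    for image_id, c in entries.items():
        rows.append(
            {
                "image_id": image_id,
                "date_min": c.date_min.date().isoformat(),
                "date_max": c.date_max.date().isoformat(),
                "granularity": c.granularity,
                "image_width_px": c.image_width_px,
                "image_height_px": c.image_height_px,
                "left": c.left,
                "right": c.right,
                "top": c.top,
                "bottom": c.bottom,
            }
        )
    return pd.DataFrame(rows)


def manifest_to_coords(frame: pd.DataFrame) -> dict[str, PlotCoordinates]:
    out = {}
    for _, row in frame.iterrows():
        out[str(row["image_id"])] = PlotCoordinates(
            date_min=pd.Timestamp(row["date_min"]),
            date_max=pd.Timestamp(row["date_max"]),
            granularity=row["granularity"],
            image_width_px=int(row["image_width_px"]),
            image_height_px=int(row["image_height_px"]),
            left=float(row["left"]),
            right=float(row["right"]),
            top=float(row["top"]),
            bottom=float(row["bottom"]),
        )
    return out
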