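"""Cleaning rules for raw crowdsourced annotation lines.

Two rules, applied in order:

1. keep only the first classification attempt per person per image, and
   at most the 41 earliest-classifying distinct people per image (the
   platform's retirement threshold can be exceeded by its scheduling);
2. merge lines drawn by the *same* person on the same image that fall
   closer than the minimum distance cutoff (7 px): such lines represent
   one change point, and are replaced by a single line at their mean
   position, green if any contributor was green.

Merging is transitive over the strictly-closer-than-cutoff graph, so it
is order independent; lines exactly the cutoff apart stay distinct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import LINE_COLUMNS, CleaningConfig


def _sorted_attempts(lines: pd.DataFrame) -> pd.DataFrame:
    order = lines.sort_values(
        ["image_id", "person_id", "attempt_time", "classification_id"],
        kind="mergesort",
    )
    return order


def keep_first_attempts(
    lines: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> pd.DataFrame:
    """First attempt per (image, person); earliest ``max_people_per_image``
    people per image.  Ordering is by attempt timestamp, ties broken by
    classification id, so the result is deterministic."""
    if lines.empty:
        return lines.copy()
    lines = lines.copy()
    lines["attempt_time"] = pd.to_datetime(lines["attempt_time"])
    ordered = _sorted_attempts(lines)

    # first classification per (image, person)
    firsts = ordered.drop_duplicates(["image_id", "person_id"])[
        ["image_id", "person_id", "attempt_time", "classification_id"]
    ]
    keep = ordered.merge(
        firsts,
        on=["image_id", "person_id", "attempt_time", "classification_id"],
        how="inner",
    )

    # cap at the earliest max_people distinct people per image
    firsts_sorted = firsts.sort_values(
        ["image_id", "attempt_time", "classification_id"], kind="mergesort"
    )
    ranked = firsts_sorted.groupby("image_id").head(config.max_people_per_image)
    allowed = set(zip(ranked["image_id"], ranked["person_id"]))
    mask = [
        (img, person) in allowed
        for img, person in zip(keep["image_id"], keep["person_id"])
    ]
    return keep.loc[mask].reset_index(drop=True)


def _merge_group(xs: np.ndarray, cutoff: float) -> np.ndarray:
    """Component label per position under the strict < cutoff relation.

    In one dimension the components of the pairwise <cutoff graph are
    the maximal runs of sorted positions with consecutive gaps < cutoff.
    """
    order = np.argsort(xs, kind="stable")
    labels = np.empty(len(xs), dtype=int)
    current = 0
    prev = None
    for i in order:
        if prev is not None and xs[i] - prev >= cutoff:
            current += 1
        labels[i] = current
        prev = xs[i]
    return labels


def merge_same_person(
    lines: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> pd.DataFrame:
    """Combine same-person lines closer than the cutoff into one line at
    the unweighted mean position, promoting colour to green if any
    contributing line was green."""
    if lines.empty:
        return lines.copy()
    cutoff = config.min_distance_cutoff_px
    out_rows = []
    for (image_id, person_id), grp in lines.groupby(
        ["image_id", "person_id"], sort=False
    ):
        xs = grp["x_px"].to_numpy(dtype=float)
        labels = _merge_group(xs, cutoff)
        for lab in np.unique(labels):
            members = grp.iloc[np.flatnonzero(labels == lab)]
            out_rows.append(
                dict(
                    image_id=image_id,
                    person_id=person_id,
                    classification_id=members["classification_id"].iloc[0],
                    attempt_time=members["attempt_time"].iloc[0],
                    x_px=float(members["x_px"].mean()),
                    colour="green" if (members["colour"] == "green").any() else "yellow",
                )
            )
    out = pd.DataFrame(out_rows, columns=LINE_COLUMNS)
    return out.sort_values(["image_id", "person_id", "x_px"], kind="mergesort").reset_index(
        drop=True
    )


def clean_lines(
    lines: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> pd.DataFrame:
    """Full cleaning: first attempts, person cap, then same-person merge."""
    return merge_same_person(keep_first_attempts(lines, config), config)
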