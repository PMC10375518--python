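"""Validation of consensus labels against expert lines.

A binary classifier is approximated over pixel positions: an expert line
matched by at least one consensus label within the minimum distance
cutoff is a true positive; an unmatched expert line a false negative; a
consensus label with no expert line within the cutoff a false positive.
True negatives are estimated per image as the number of cutoff-width
intervals across the plot area (the maximum number of distinguishable
change points, 136 by default) minus the other three counts.  The
double-counting rules follow from the definitions: several labels near
one expert line give one TP and no FP; one label near two expert lines
gives two TPs and no FN.

Metrics are sensitivity, specificity, PPV and NPV with Wilson score 95%
confidence intervals, plus the Matthews correlation coefficient (MCC),
which also drives the grid search over the consensus parameters
(include-yellow x min-lines-in-cluster 2..20 x eps 1..7 px).
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .consensus import consensus_labels
from .types import ConfusionCounts, ConsensusParams, MetricSet

DEFAULT_CUTOFF_PX = 7.0
DEFAULT_PLOT_WIDTH_PX = 952.0
#: floor(952 / 7): cutoff-width slots across the candidate region.
DEFAULT_INTERVALS_PER_IMAGE = int(DEFAULT_PLOT_WIDTH_PX // DEFAULT_CUTOFF_PX)


def match_labels_image(
    label_px: Sequence[float],
    expert_px: Sequence[float],
    cutoff_px: float = DEFAULT_CUTOFF_PX,
    intervals_per_image: int = DEFAULT_INTERVALS_PER_IMAGE,
) -> ConfusionCounts:
    """Confusion counts for a single image.

    A label and an expert line match when they are strictly closer than
    ``cutoff_px`` (lines exactly the cutoff apart are distinct change
    points).
    """
    labels = np.asarray(label_px, dtype=float)
    expert = np.asarray(expert_px, dtype=float)
    if len(expert) and len(labels):
        dist = np.abs(expert[:, None] - labels[None, :])
        expert_hit = (dist < cutoff_px).any(axis=1)
        label_hit = (dist < cutoff_px).any(axis=0)
    else:
        expert_hit = np.zeros(len(expert), dtype=bool)
        label_hit = np.zeros(len(labels), dtype=bool)
    tp = int(expert_hit.sum())
    fn = int(len(expert) - tp)
    fp = int((~label_hit).sum())
    tn = intervals_per_image - (tp + fp + fn)
    if tn < 0:
        raise ValueError(
            f"negative TN ({tn}): intervals_per_image={intervals_per_image} too small"
        )
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def match_labels(
    labels: pd.DataFrame,
    expert: pd.DataFrame,
    cutoff_px: float = DEFAULT_CUTOFF_PX,
    intervals_per_image: int = DEFAULT_INTERVALS_PER_IMAGE,
    image_ids: Optional[Iterable[str]] = None,
) -> ConfusionCounts:
    """Pool per-image confusion counts over a set of images.

    ``labels`` and ``expert`` are tables with ``image_id`` and ``x_px``
    columns.  ``image_ids`` fixes the image universe (an image with no
    lines at all still contributes its true-negative intervals); by
    default it is the union of images seen in either table.
    """
    if image_ids is None:
        image_ids = sorted(
            set(labels["image_id"].astype(str)) | set(expert["image_id"].astype(str))
        )
    lab_by = {k: g["x_px"].to_numpy(float) for k, g in labels.groupby(labels["image_id"].astype(str))}
    exp_by = {k: g["x_px"].to_numpy(float) for k, g in expert.groupby(expert["image_id"].astype(str))}
    total = ConfusionCounts(0, 0, 0, 0)
    for image_id in image_ids:
        total = total + match_labels_image(
            lab_by.get(str(image_id), ()),
            exp_by.get(str(image_id), ()),
            cutoff_px=cutoff_px,
            intervals_per_image=intervals_per_image,
        )
    return total


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal sum is 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom_terms = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(t == 0 for t in denom_terms):
        return 0.0
    num = tp * tn - fp * fn
    return num / math.sqrt(math.prod(float(t) for t in denom_terms))


def _wilson(count: int, nobs: int) -> Optional[tuple[float, float]]:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV (with Wilson 95% CIs) and MCC."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(a: int, b: int) -> Optional[float]:
        return a / b if b else None

    ci = {}
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        interval = _wilson(num, den)
        if interval is not None:
            ci[name] = interval
    return MetricSet(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        mcc=mcc(counts),
        ci_95=ci,
    )


def split_images(
    image_extracts: Mapping[str, str] | pd.DataFrame,
    tuning_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random tuning/test split of images, balanced by extract.

    Within each extract, round(tuning_fraction * size) images (round half
    up) go to tuning.  Extracts with a single image go entirely to tuning
    with a warning.
    """
    import warnings

    if isinstance(image_extracts, pd.DataFrame):
        pairs = list(zip(image_extracts["image_id"].astype(str),
                         image_extracts["extract_id"].astype(str)))
    else:
        pairs = [(str(k), str(v)) for k, v in image_extracts.items()]
    rng = np.random.default_rng(seed)
    tuning: list[str] = []
    test: list[str] = []
    by_extract: dict[str, list[str]] = {}
    for image_id, extract in pairs:
        by_extract.setdefault(extract, []).append(image_id)
    for extract in sorted(by_extract):
        imgs = sorted(by_extract[extract])
        if len(imgs) < 2:
            warnings.warn(
                f"extract {extract!r} has {len(imgs)} image(s); assigning all to tuning"
            )
            tuning.extend(imgs)
            continue
        perm = rng.permutation(len(imgs))
        k = int(math.floor(tuning_fraction * len(imgs) + 0.5))
        tuning.extend(imgs[i] for i in perm[:k])
        test.extend(imgs[i] for i in perm[k:])
    return sorted(tuning), sorted(test)


def parameter_grid(
    min_pts_range: Sequence[int] = range(2, 21),
    eps_range: Sequence[float] = range(1, 8),
) -> list[ConsensusParams]:
    """The 2 x 19 x 7 = 266 combinations searched during tuning."""
    return [
        ConsensusParams(include_yellow=iy, min_pts=mp, eps_px=float(eps))
        for iy, mp, eps in itertools.product(
            (False, True), min_pts_range, eps_range
        )
    ]


def tune_grid(
    cleaned_lines: pd.DataFrame,
    expert_lines: pd.DataFrame,
    image_ids: Sequence[str],
    cutoff_px: float = DEFAULT_CUTOFF_PX,
    intervals_per_image: int = DEFAULT_INTERVALS_PER_IMAGE,
    grid: Optional[Sequence[ConsensusParams]] = None,
) -> pd.DataFrame:
    """Grid-search the consensus parameters by pooled MCC on the tuning set.

    Returns one row per parameter combination with its pooled confusion
    counts and metrics, sorted by MCC descending; ties broken by smaller
    min_pts, then smaller eps, then exclude-yellow first, so the ranking
    is deterministic and independent of image processing order.
    """
    if grid is None:
        grid = parameter_grid()
    image_ids = [str(i) for i in image_ids]
    lines = cleaned_lines[cleaned_lines["image_id"].astype(str).isin(image_ids)]
    expert = expert_lines[expert_lines["image_id"].astype(str).isin(image_ids)]
    rows = []
    for params in grid:
        labels = consensus_labels(lines, params)
        counts = match_labels(
            labels, expert, cutoff_px=cutoff_px,
            intervals_per_image=intervals_per_image, image_ids=image_ids,
        )
        m = metrics(counts)
        rows.append(
            dict(
                include_yellow=params.include_yellow,
                min_pts=params.min_pts,
                eps_px=params.eps_px,
                tp=counts.tp, tn=counts.tn, fp=counts.fp, fn=counts.fn,
                mcc=m.mcc,
                sensitivity=m.sensitivity, specificity=m.specificity,
                ppv=m.ppv, npv=m.npv,
            )
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["mcc", "min_pts", "eps_px", "include_yellow"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def min_distance_distribution(lines: pd.DataFrame) -> pd.DataFrame:
    """Minimum pairwise distance between lines drawn by one volunteer on
    one image (pre-merge, first attempts), for cutoff selection.

    Returns one row per (image, person) with >= 2 lines.  Use
    :func:`min_distance_histogram` to bin the values into left-closed,
    right-open integer intervals.
    """
    rows = []
    for (image_id, person_id), grp in lines.groupby(["image_id", "person_id"]):
        xs = np.sort(grp["x_px"].to_numpy(dtype=float))
        if len(xs) < 2:
            continue
        rows.append(
            dict(
                image_id=image_id,
                person_id=person_id,
                min_distance_px=float(np.diff(xs).min()),
            )
        )
    return pd.DataFrame(rows, columns=["image_id", "person_id", "min_distance_px"])


def min_distance_histogram(
    distances: Sequence[float], max_px: Optional[int] = None
) -> pd.DataFrame:
    """Histogram with integer bins [k, k+1), closed left, open right."""
    d = np.asarray(distances, dtype=float)
    if max_px is None:
        max_px = int(np.floor(d.max())) + 1 if len(d) else 1
    edges = np.arange(0, max_px + 1)
    # np.histogram closes the last bin on the right; pad one bin to keep
    # every reported bin half-open
    counts, _ = np.histogram(d, bins=np.append(edges, edges[-1] + 1))
    return pd.DataFrame(
        {"bin_left": edges, "bin_right": edges + 1, "count": counts[: len(edges)]}
    )
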