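"""Consensus change-point labels via 1-D density-based clustering with noise.

Cleaned annotation lines on an image form a 1-D point set of x-pixels.
A point is a *core* point when at least ``min_pts`` points (itself
included) lie within ``eps_px`` of it; clusters are the connected
components of core points under the <= eps relation, plus *border*
points (non-core points within eps of a core point, assigned to the
cluster of their nearest core point, ties to the lower cluster id);
everything else is noise and is ignored.  The unweighted mean position
of each cluster becomes the consensus label, converted back to a date
through the image's plot geometry.

:class:`DBSCAN1D` follows the scikit-learn clusterer API (``fit``,
``fit_predict``, ``labels_``, ``core_sample_indices_``) so it composes
with sklearn tooling; the exact 1-D algorithm runs in O(n log n).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .render import PlotCoordinates, px_to_timepoint
from .types import LABEL_COLUMNS, ConsensusParams


class DBSCAN1D(ClusterMixin, BaseEstimator):
    """Exact density-based clustering with noise for one-dimensional data.

    Parameters
    ----------
    eps : float
        Maximum distance between two points in a cluster (inclusive).
    min_samples : int
        Minimum number of points (including the point itself) within
        ``eps`` of a point for it to be a core point.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster id per point, numbered left to right from 0; noise is -1.
    core_sample_indices_ : ndarray
        Indices of core points.
    """

    def __init__(self, eps: float = 3.0, min_samples: int = 5):
        self.eps = eps
        self.min_samples = min_samples

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.asarray(X).ndim == 2:
            if np.asarray(X).shape[1] != 1:
                raise ValueError("DBSCAN1D accepts a single feature")
            x = np.asarray(X, dtype=float)[:, 0]
        if not np.all(np.isfinite(x)):
            raise ValueError("positions must be finite")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")

        n = len(x)
        labels = np.full(n, -1, dtype=int)
        if n == 0:
            self.labels_ = labels
            self.core_sample_indices_ = np.array([], dtype=int)
            return self

        order = np.argsort(x, kind="stable")
        xs = x[order]
        # neighbour count within eps, inclusive on both ends
        left = np.searchsorted(xs, xs - self.eps, side="left")
        right = np.searchsorted(xs, xs + self.eps, side="right")
        n_neighbors = right - left
        core_sorted = n_neighbors >= self.min_samples

        core_pos = np.flatnonzero(core_sorted)
        labels_sorted = np.full(n, -1, dtype=int)
        if len(core_pos):
            # components of core points: consecutive cores <= eps apart chain up
            gaps = np.diff(xs[core_pos])
            comp = np.concatenate([[0], np.cumsum(gaps > self.eps)])
            labels_sorted[core_pos] = comp
            n_clusters = comp[-1] + 1

            # border points: non-core within eps of a core; nearest core wins,
            # ties to the lower cluster id
            core_x = xs[core_pos]
            core_lab = labels_sorted[core_pos]
            for i in np.flatnonzero(~core_sorted):
                j = np.searchsorted(core_x, xs[i])
                best_lab, best_d = -1, np.inf
                for k in (j - 1, j):
                    if 0 <= k < len(core_x):
                        d = abs(xs[i] - core_x[k])
                        if d <= self.eps and (
                            d < best_d or (d == best_d and core_lab[k] < best_lab)
                        ):
                            best_d, best_lab = d, core_lab[k]
                labels_sorted[i] = best_lab
        labels[order] = labels_sorted
        self.labels_ = labels
        self.core_sample_indices_ = np.sort(order[np.flatnonzero(core_sorted)])
        return self


def dbscan_1d(positions, min_pts: int, eps_px: float) -> np.ndarray:
    """Cluster assignment per position (noise = -1); see :class:`DBSCAN1D`."""
    return DBSCAN1D(eps=eps_px, min_samples=min_pts).fit(positions).labels_


class ImageLookupError(KeyError):
    pass


def consensus_labels(
    lines: pd.DataFrame,
    params: ConsensusParams,
    coords: Optional[Mapping[str, PlotCoordinates]] = None,
) -> pd.DataFrame:
    """Consensus change-point labels per image.

    Yellow (uncertain) lines are dropped first when ``include_yellow``
    is false; the remaining x-pixels are clustered per image; each
    cluster yields one label at the unweighted mean pixel with its
    contributor count, converted to the nearest timepoint-interval start
    when plot geometry is supplied.  Images may yield zero labels.
    """
    rows = []
    if not lines.empty:
        work = lines if params.include_yellow else lines[lines["colour"] == "green"]
        for image_id, grp in work.groupby("image_id", sort=True):
            xs = grp["x_px"].to_numpy(dtype=float)
            labels = dbscan_1d(xs, params.min_pts, params.eps_px)
            c: Optional[PlotCoordinates] = None
            if coords is not None:
                try:
                    c = coords[image_id]
                except KeyError:
                    raise ImageLookupError(
                        f"image {image_id!r} missing from the coordinates manifest"
                    ) from None
            for lab in np.unique(labels[labels >= 0]):
                member = xs[labels == lab]
                x_mean = float(member.mean())
                date = (
                    px_to_timepoint(x_mean, c).date().isoformat()
                    if c is not None
                    else None
                )
                rows.append(
                    dict(
                        image_id=image_id,
                        x_px=x_mean,
                        n_contributors=int(len(member)),
                        date=date,
                    )
                )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)
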