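"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the clustering
oracle is a quadratic pairwise computation using scipy's connected
components, and the matching oracle is plain Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_density_cluster(
    positions, min_pts: int, eps: float
) -> np.ndarray:
    """Quadratic reference for 1-D density-based clustering with noise.

    Core point: >= min_pts points (itself included) within eps
    (inclusive).  Clusters: connected components of core points under
    the <= eps relation, numbered left to right by their leftmost core
    point.  Border points join the cluster of their nearest core point,
    ties to the lower cluster id; all else is noise (-1).
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    dist = np.abs(x[:, None] - x[None, :])
    within = dist <= eps
    core = within.sum(axis=1) >= min_pts
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels
    adj = within[np.ix_(core_idx, core_idx)]
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    # renumber components left to right by their leftmost member
    leftmost = [x[core_idx[comp == c]].min() for c in range(n_comp)]
    rank = np.argsort(np.argsort(leftmost, kind="stable"), kind="stable")
    comp = rank[comp]
    labels[core_idx] = comp
    for i in np.flatnonzero(~core):
        ds = dist[i, core_idx]
        ok = ds <= eps
        if not ok.any():
            continue
        best = np.min(ds[ok])
        candidates = comp[ok & (ds == best)]
        labels[i] = int(candidates.min())
    return labels


def brute_force_confusion(label_px, expert_px, cutoff, intervals):
    """Pure-Python per-image confusion counts oracle."""
    tp = 0
    for e in expert_px:
        if any(abs(e - l) < cutoff for l in label_px):
            tp += 1
    fn = len(expert_px) - tp
    fp = 0
    for l in label_px:
        if not any(abs(e - l) < cutoff for e in expert_px):
            fp += 1
    tn = intervals - tp - fp - fn
    return tp, tn, fp, fn
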