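"""Half-open integer interval sets on a single chromosome.

Interval sets are represented as ``(n, 2)`` int64 arrays of 0-based
half-open ``[start, end)`` rows.  All functions return merged (disjoint,
sorted) arrays.  These are thin numpy helpers used for site masks; they
are deliberately minimal rather than a general interval container.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "union",
    "dilate",
    "total_length",
    "contains",
    "masked_count_below",
    "clip",
]


def as_intervals(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if a.size and np.any(a[:, 1] < a[:, 0]):
        raise ValueError("interval end < start")
    return a


def merge(ivals) -> np.ndarray:
    """Sort and merge overlapping or adjacent intervals."""
    a = as_intervals(ivals)
    a = a[a[:, 1] > a[:, 0]]  # zero-length intervals cover no positions
    if len(a) == 0:
        return a
    a = a[np.argsort(a[:, 0], kind="stable")]
    out = [a[0].copy()]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def union(*interval_sets) -> np.ndarray:
    parts = [as_intervals(x) for x in interval_sets if len(as_intervals(x))]
    if not parts:
        return np.empty((0, 2), dtype=np.int64)
    return merge(np.concatenate(parts))


def dilate(ivals, radius: int, lo: int = 0, hi: int | None = None) -> np.ndarray:
    """Expand every interval by ``radius`` bases on both sides.

    Positions are clipped to ``[lo, hi)`` when bounds are given.
    Dilation is monotone: a larger radius never unmasks a site.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    a = merge(ivals)
    if len(a) == 0:
        return a
    b = a.copy()
    b[:, 0] -= radius
    b[:, 1] += radius
    b[:, 0] = np.maximum(b[:, 0], lo)
    if hi is not None:
        b[:, 1] = np.minimum(b[:, 1], hi)
    return merge(b)


def total_length(ivals) -> int:
    a = as_intervals(ivals)
    return int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0


def contains(ivals, positions) -> np.ndarray:
    """Boolean array: is each position inside the interval set?"""
    a = merge(ivals)
    pos = np.asarray(positions, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(pos.shape, dtype=bool)
    # position p is covered iff an odd number of boundary points <= p
    bounds = a.reshape(-1)
    idx = np.searchsorted(bounds, pos, side="right")
    return idx % 2 == 1


def masked_count_below(ivals, positions) -> np.ndarray:
    """Number of masked integer sites strictly below each position.

    ``ivals`` must be merged.  Vectorized; used for computing unmasked
    site counts between arbitrary physical boundaries.
    """
    a = as_intervals(ivals)
    pos = np.asarray(positions, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(pos.shape, dtype=np.int64)
    starts, ends = a[:, 0], a[:, 1]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    i = np.searchsorted(starts, pos, side="right")
    full = cum[i]
    # subtract the part of interval i-1 at or beyond pos
    over = np.where(i > 0, np.maximum(ends[np.maximum(i - 1, 0)] - pos, 0), 0)
    return full - np.minimum(over, np.where(i > 0, ends[np.maximum(i - 1, 0)] - starts[np.maximum(i - 1, 0)], 0))


def clip(ivals, lo: int, hi: int) -> np.ndarray:
    """Restrict an interval set to ``[lo, hi)``."""
    a = merge(ivals)
    if len(a) == 0:
        return a
    b = a[(a[:, 1] > lo) & (a[:, 0] < hi)].copy()
    if len(b) == 0:
        return np.empty((0, 2), dtype=np.int64)
    b[:, 0] = np.maximum(b[:, 0], lo)
    b[:, 1] = np.minimum(b[:, 1], hi)
    return b
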