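"""Small interval utilities shared across modules.

All intervals are 0-based half-open ``(start, end)`` pairs on one chromosome,
represented either as a list of tuples or as parallel start/end arrays that
are sorted and non-overlapping.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_arrays",
    "merge_intervals",
    "clip_out",
    "intersect",
    "total_length",
    "covers",
    "coverage_in_window",
]


def as_arrays(intervals) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(intervals, tuple) and len(intervals) == 2 and np.ndim(intervals[0]) == 1:
        starts, ends = intervals
        return np.asarray(starts, np.int64), np.asarray(ends, np.int64)
    if len(intervals) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    arr = np.asarray(intervals, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def merge_intervals(intervals, gap: int = 0) -> list[tuple[int, int]]:
    """Sort and merge overlapping (or within ``gap`` bp) intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def clip_out(intervals, holes) -> list[tuple[int, int]]:
    """Remove ``holes`` from ``intervals`` (set difference)."""
    holes = merge_intervals(holes)
    out = []
    for s, e in merge_intervals(intervals):
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, min(hs, e)))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a, b) -> list[tuple[int, int]]:
    """Set intersection of two interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def covers(intervals, positions: np.ndarray) -> np.ndarray:
    """Boolean mask: which ``positions`` fall inside the intervals."""
    starts, ends = as_arrays(merge_intervals(intervals))
    positions = np.asarray(positions, np.int64)
    if starts.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    k = np.searchsorted(starts, positions, side="right") - 1
    ok = k >= 0
    out = np.zeros(positions.shape, dtype=bool)
    out[ok] = positions[ok] < ends[k[ok]]
    return out


def coverage_in_window(intervals, start: int, end: int) -> int:
    """Total bp of the intervals overlapping ``[start, end)``."""
    return total_length(intersect(intervals, [(start, end)]))
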