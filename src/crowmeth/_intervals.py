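"""Small interval utilities on 0-based half-open coordinates.

All functions operate on integer numpy arrays of shape (k, 2) per
chromosome; callers handle the chromosome grouping.
"""

from __future__ import annotations

import numpy as np


def merge(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or touching intervals. Returns sorted (k, 2) array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=int)
    iv = np.asarray(intervals, dtype=int)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=int)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Portions of intervals `a` not covered by intervals `b`."""
    a = merge(a)
    b = merge(b)
    if len(a) == 0:
        return a
    if len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=int) if out else np.empty((0, 2), dtype=int)


def total_length(intervals: np.ndarray) -> int:
    m = merge(intervals)
    if len(m) == 0:
        return 0
    return int((m[:, 1] - m[:, 0]).sum())


def overlap_length(intervals: np.ndarray, start: int, end: int) -> int:
    """Total bases of `intervals` falling inside [start, end)."""
    if len(intervals) == 0:
        return 0
    iv = np.asarray(intervals, dtype=int)
    lo = np.maximum(iv[:, 0], start)
    hi = np.minimum(iv[:, 1], end)
    return int(np.maximum(hi - lo, 0).sum())
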