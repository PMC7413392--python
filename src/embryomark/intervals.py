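"""Half-open genomic interval arithmetic on sorted numpy arrays.

All functions operate on intervals within a single chromosome, represented as
two equal-length integer arrays ``starts`` and ``ends`` with the BED
convention: 0-based, half-open ``[start, end)``.  Callers are responsible for
splitting by chromosome.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge", "total_length", "overlap_length", "subtract_from"]


def merge(starts, ends):
    """Merge overlapping or bookended intervals into a disjoint sorted set.

    Returns (starts, ends) arrays of the merged intervals.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(starts, ends):
    """Sum of interval lengths (assumes disjoint intervals)."""
    return int(np.sum(np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)))


def overlap_length(start, end, m_starts, m_ends):
    """Bases of ``[start, end)`` covered by a merged (disjoint, sorted) set."""
    if len(m_starts) == 0 or end <= start:
        return 0
    lo = np.maximum(np.asarray(m_starts), start)
    hi = np.minimum(np.asarray(m_ends), end)
    return int(np.sum(np.clip(hi - lo, 0, None)))


def subtract_from(start, end, m_starts, m_ends):
    """Fragments of ``[start, end)`` not covered by a merged set.

    Returns a list of (start, end) tuples, in coordinate order.
    """
    frags = []
    cur = start
    for ms, me in zip(m_starts, m_ends):
        if me <= cur:
            continue
        if ms >= end:
            break
        if ms > cur:
            frags.append((cur, min(ms, end)))
        cur = max(cur, me)
        if cur >= end:
            break
    if cur < end:
        frags.append((cur, end))
    return frags
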