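"""Half-open interval arithmetic on genomic coordinates.

All intervals are 0-based half-open ``(start, end)`` tuples with
``start < end``. Functions returning interval lists always return them
sorted and merged (non-overlapping, non-adjacent).
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or abutting intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intersection of two merged interval lists (two-pointer sweep)."""
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intersect(a, b))


def contains(container: Sequence[Interval], contained: Sequence[Interval]) -> bool:
    """True iff the union of ``contained`` lies within the union of ``container``."""
    need = total_length(contained)
    return intersect_length(container, contained) == need


def is_sorted_disjoint(intervals: Sequence[Interval]) -> bool:
    """True iff intervals are sorted, non-empty and pairwise non-overlapping."""
    prev_end = None
    for s, e in intervals:
        if e <= s:
            return False
        if prev_end is not None and s < prev_end:
            return False
        prev_end = e
    return True


def complement(intervals: Sequence[Interval], start: int, end: int) -> List[Interval]:
    """Gaps of the merged intervals within ``[start, end)``."""
    out: List[Interval] = []
    cursor = start
    for s, e in merge(intervals):
        if s > cursor:
            out.append((cursor, min(s, end)))
        cursor = max(cursor, e)
        if cursor >= end:
            break
    if cursor < end:
        out.append((cursor, end))
    return [iv for iv in out if iv[0] < iv[1]]
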