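"""Exact closed-open interval arithmetic on (start, end) float pairs."""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[float, float]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and coalesce overlapping/abutting intervals; drops empties."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> float:
    return sum(e - s for s, e in merge(intervals))


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Set difference a \\ b, both treated as unions of closed-open intervals."""
    result: list[Interval] = []
    b_merged = merge(b)
    for s, e in merge(a):
        cur = s
        for bs, be in b_merged:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                result.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            result.append((cur, e))
    return result


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    bm = merge(b)
    for s, e in merge(a):
        for bs, be in bm:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                out.append((lo, hi))
    return merge(out)


def overlaps(iv: Interval, others: Sequence[Interval]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in others)
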