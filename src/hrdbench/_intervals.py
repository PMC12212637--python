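"""Low-level half-open interval arithmetic shared across modules.

All functions operate on flat lists of ``(start, end)`` tuples with
0-based half-open coordinates on a single chromosome; callers are
responsible for grouping by chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals: sorted, overlapping/abutting runs coalesced."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(interval: tuple[int, int], cuts: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of ``interval`` not covered by ``cuts`` (cuts must be merged/sorted)."""
    s, e = interval
    out = []
    pos = s
    for cs, ce in cuts:
        if ce <= pos:
            continue
        if cs >= e:
            break
        if cs > pos:
            out.append((pos, cs))
        pos = max(pos, ce)
        if pos >= e:
            break
    if pos < e:
        out.append((pos, e))
    return out


def intersect_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total overlap length between two merged, sorted interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def total_length(a: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in a)
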