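"""Half-open integer interval arithmetic on ``[start, end)`` pairs (ms)."""

from __future__ import annotations


def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent intervals; drop empty ones."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: list[tuple[int, int]],
             remove: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference base \\ remove, both as half-open interval lists."""
    remove = merge(remove)
    out: list[tuple[int, int]] = []
    for s, e in merge(base):
        cur = s
        for rs, re in remove:
            if re <= cur:
                continue
            if rs >= e:
                break
            if rs > cur:
                out.append((cur, min(rs, e)))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: list[tuple[int, int]],
              b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    a, b = merge(a), merge(b)
    out: list[tuple[int, int]] = []
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


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge(intervals))
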