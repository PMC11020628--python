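"""0-based half-open genomic intervals.

All internal coordinates in this package are 0-based half-open; conversion
to 1-based inclusive happens only when writing GFF3.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple


@dataclass(frozen=True, order=True)
class Interval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)

    def hull(self, other: "Interval") -> "Interval":
        return Interval(min(self.start, other.start), max(self.end, other.end))


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total length covered by the union of (start, end) pairs."""
    pairs = sorted((s, e) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in pairs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def reciprocal_overlap(a: Interval, b: Interval, threshold: float) -> bool:
    """True when the overlap covers at least ``threshold`` of BOTH intervals."""
    ov = a.overlap_length(b)
    if len(a) == 0 or len(b) == 0:
        return False
    return ov >= threshold * len(a) and ov >= threshold * len(b)


def subtract(a: Interval, removed: Iterable[Interval]) -> List[Interval]:
    """Pieces of ``a`` not covered by ``removed``."""
    pieces = [a]
    for r in sorted(removed, key=lambda x: x.start):
        nxt: List[Interval] = []
        for p in pieces:
            if not p.overlaps(r):
                nxt.append(p)
                continue
            if p.start < r.start:
                nxt.append(Interval(p.start, r.start))
            if r.end < p.end:
                nxt.append(Interval(r.end, p.end))
        pieces = nxt
    return pieces
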