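"""Signature filters and TSD post-processing.

An element survives only if: its LTRs are 200-7,000 bp and the internal
part >= 200 bp (nested spans excluded); the LTRs have comparable length or
a rescuing local alignment (>= 80 bp at >= 80% identity); a polypurine
tract fires in the internal part (or its reversed-orientation counterpart);
and at most one of its LTRs looks like a MITE (terminal inverted repeat).
Solo LTRs whose component retains no surviving element are dropped.
Finally, a target-site duplication (longest common substring of the 20-bp
flanks, >= 4 bp) is annotated and the element widened to touch it.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from ._kmers import reverse_complement
from .intervals import Interval, subtract
from .matcher import ElementCandidate, SoloCandidate


@dataclass(frozen=True)
class FilterConfig:
    min_ltr: int = 200
    max_ltr: int = 7000
    min_internal: int = 200
    min_len_ratio: float = 0.8
    sw_min_len: int = 80
    sw_min_sim: float = 0.80
    ppt_window: int = 400
    ppt_probe: int = 100
    ppt_min_align: int = 12
    mite_tail: int = 30
    mite_min_align: int = 15
    mite_min_sim: float = 0.85
    tsd_flank: int = 20
    tsd_min: int = 4

    def __post_init__(self) -> None:
        if min(
            self.min_ltr,
            self.max_ltr,
            self.min_internal,
            self.sw_min_len,
            self.ppt_window,
            self.ppt_probe,
            self.ppt_min_align,
            self.mite_tail,
            self.mite_min_align,
            self.tsd_flank,
            self.tsd_min,
        ) <= 0:
            raise ValueError("all filter lengths must be positive")
        for r in (self.min_len_ratio, self.sw_min_sim, self.mite_min_sim):
            if not 0 < r <= 1:
                raise ValueError("ratios must lie in (0, 1]")


@lru_cache(maxsize=1)
def _local_aligner() -> Align.PairwiseAligner:
    # match +2, mismatch -1, gap open -2, extend -1
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _best_local(a: str, b: str) -> Tuple[int, float, Tuple[int, int]]:
    """(alignment length, identity, matched span in `b`) of the best local
    alignment, or (0, 0.0, (0, 0)) when nothing aligns."""
    if not a or not b:
        return 0, 0.0, (0, 0)
    alignments = _local_aligner().align(a, b)
    if alignments.score <= 0:
        return 0, 0.0, (0, 0)
    aln = alignments[0]
    counts = aln.counts()
    length = aln.length
    if length == 0:
        return 0, 0.0, (0, 0)
    b_start = int(aln.coordinates[1][0])
    b_end = int(aln.coordinates[1][-1])
    return length, counts.identities / length, (b_start, b_end)


def _has_dense_window(a: str, b: str, min_len: int, min_sim: float, strict_len: bool = False) -> bool:
    """True when the best local alignment of ``a`` and ``b`` contains a
    contiguous window of columns of at least ``min_len`` whose identity
    exceeds ``min_sim``.

    The max-score traceback dilutes dense cores with low-identity
    extensions (a match/mismatch of +2/-1 profits from ~33% density), so
    the criteria are evaluated over sub-windows rather than the whole
    alignment.
    """
    if not a or not b:
        return False
    alignments = _local_aligner().align(a, b)
    if alignments.score <= 0:
        return False
    aln = alignments[0]
    idx = aln.indices
    match = np.array(
        [i0 >= 0 and i1 >= 0 and a[i0] == b[i1] for i0, i1 in zip(idx[0], idx[1])],
        dtype=float,
    )
    n = match.size
    cum = np.concatenate(([0.0], np.cumsum(match)))
    start = min_len + 1 if strict_len else min_len
    for length in range(start, n + 1):
        window = cum[length:] - cum[:-length]
        if window.size == 0:
            continue
        frac = window.max() / length
        if (frac > min_sim) if strict_len else (frac >= min_sim):
            return True
    return False


def check_lengths(element: ElementCandidate, config: FilterConfig = FilterConfig()) -> bool:
    """LTRs in [200, 7000), internal >= 200 bp with nested spans excluded."""
    for ltr in (element.ltr5, element.ltr3):
        if not (config.min_ltr <= len(ltr) < config.max_ltr):
            return False
    nested = [c.span for c in element.children]
    internal_len = sum(len(p) for p in subtract(element.internal, nested))
    return internal_len >= config.min_internal


def check_similarity(element: ElementCandidate, sequence: str, config: FilterConfig = FilterConfig()) -> bool:
    """Comparable LTR lengths, or a rescuing Smith-Waterman alignment."""
    a = sequence[element.ltr5.start : element.ltr5.end]
    b = sequence[element.ltr3.start : element.ltr3.end]
    if not a or not b:
        return False
    if min(len(a), len(b)) / max(len(a), len(b)) >= config.min_len_ratio:
        return True
    return _has_dense_window(a, b, config.sw_min_len, config.sw_min_sim)


def find_ppt(
    element: ElementCandidate,
    sequence: str,
    config: FilterConfig = FilterConfig(),
) -> Optional[Tuple[Interval, bool]]:
    """Locate the polypurine tract; returns (interval, reversed_flag).

    Plus-strand search: the last <=400 bp of the internal part before the
    3' LTR, G mapped to A, locally aligned against a 100-bp poly-A probe;
    a hit needs alignment length > 12 and strictly more A than G in the
    matched region of the original sequence.  Failing that, the reversed
    hypothesis is tried with T/C downstream of the 5' LTR.
    """
    internal = element.internal
    if len(internal) < 1:
        return None

    def try_orientation(window: Interval, purine: str, mapped_from: str) -> Optional[Interval]:
        raw = sequence[window.start : window.end]
        if not raw:
            return None
        mapped = raw.replace(mapped_from, purine)
        probe = purine * config.ppt_probe
        length, _, (b_start, b_end) = _best_local(probe, mapped)
        if length <= config.ppt_min_align:
            return None
        region = raw[b_start:b_end]
        if region.count(purine) <= region.count(mapped_from):
            return None
        return Interval(window.start + b_start, window.start + b_end)

    w = min(config.ppt_window, len(internal))
    plus_window = Interval(internal.end - w, internal.end)
    hit = try_orientation(plus_window, "A", "G")
    if hit is not None:
        return hit, False
    minus_window = Interval(internal.start, internal.start + w)
    hit = try_orientation(minus_window, "T", "C")
    if hit is not None:
        return hit, True
    return None


def is_mite(element: ElementCandidate, sequence: str, config: FilterConfig = FilterConfig()) -> bool:
    """True when BOTH LTR candidates carry terminal inverted repeats."""

    def ltr_is_mite(iv: Interval) -> bool:
        s = sequence[iv.start : iv.end]
        if len(s) < 2 * config.mite_tail:
            return False
        head = s[: config.mite_tail]
        tail = reverse_complement(s[-config.mite_tail :])
        return _has_dense_window(
            head, tail, config.mite_min_align, config.mite_min_sim, strict_len=True
        )

    return ltr_is_mite(element.ltr5) and ltr_is_mite(element.ltr3)


def filter_element(
    element: ElementCandidate,
    sequence: str,
    config: FilterConfig = FilterConfig(),
) -> Tuple[bool, Optional[Tuple[Interval, bool]]]:
    """Conjunction of all element filters; returns (passed, ppt_hit)."""
    if not check_lengths(element, config):
        return False, None
    if not check_similarity(element, sequence, config):
        return False, None
    ppt = find_ppt(element, sequence, config)
    if ppt is None:
        return False, None
    if is_mite(element, sequence, config):
        return False, None
    return True, ppt


def drop_orphan_solos(
    solos: Sequence[SoloCandidate],
    surviving_elements: Sequence[ElementCandidate],
) -> List[SoloCandidate]:
    """Keep a solo LTR only if its connected component retained an element."""
    alive = {e.component_id for e in surviving_elements}
    return [s for s in solos if s.component_id in alive]


def longest_common_substring(a: str, b: str) -> List[Tuple[int, int, int]]:
    """All (start_a, start_b, length) of maximal-length common substrings."""
    if not a or not b:
        return []
    best = 0
    hits: List[Tuple[int, int, int]] = []
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    hits = [(i - best, j - best, best)]
                elif cur[j] == best and best > 0:
                    hits.append((i - best, j - best, best))
        prev = cur
    return hits


def find_tsd(
    element: ElementCandidate,
    sequence: str,
    config: FilterConfig = FilterConfig(),
) -> Optional[Tuple[Interval, Interval]]:
    """Longest common substring (>= 4 bp) of the two 20-bp flanks; the
    element is widened in place to touch the TSD copies."""
    span = element.span
    up = Interval(max(0, span.start - config.tsd_flank), span.start)
    down = Interval(span.end, min(len(sequence), span.end + config.tsd_flank))
    a = sequence[up.start : up.end]
    b = sequence[down.start : down.end]
    hits = longest_common_substring(a, b)
    if not hits or hits[0][2] < config.tsd_min:
        return None
    # ties resolve to the pair closest to the element boundaries
    def distance(hit: Tuple[int, int, int]) -> int:
        sa, sb, ln = hit
        return (len(a) - (sa + ln)) + sb

    sa, sb, ln = min(hits, key=distance)
    left = Interval(up.start + sa, up.start + sa + ln)
    right = Interval(down.start + sb, down.start + sb + ln)
    # widen the element to meet the TSD
    if left.end < span.start:
        element.ltr5 = Interval(left.end, element.ltr5.end)
    if right.start > span.end:
        element.ltr3 = Interval(element.ltr3.start, right.start)
    return left, right
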