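"""Grouping score tracks into stretches and the seven-step merge.

Steps, in order: (1) group runs of the same exact non-zero score into
stretches; (2) label by size (>= 16 bp -> keep, else delete); (3) merge
adjacent stretches whose heights differ by less than the similarity margin
and whose gap is smaller than the margin; (4) remove interruptive
delete-labeled stretches sitting between two stretches that would merge
without them; (5) merge again; (6) remove remaining delete stretches;
(7) merge again.  The similarity margin is the mean within-LTR gap size
plus three standard deviations, rounded to the nearest bp.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .intervals import Interval
from .scorer import ScoreTrack

DEFAULT_GAP_MEAN = 16.30
DEFAULT_GAP_SD = 19.62
DEFAULT_KEEP_THRESHOLD = 16


def compute_margin(gap_mean: float, gap_sd: float) -> int:
    """Similarity margin: round(mean + 3 * sd).  (16.30, 19.62) -> 75."""
    if gap_mean < 0 or gap_sd < 0:
        raise ValueError("gap statistics must be non-negative")
    return int(round(gap_mean + 3.0 * gap_sd))


@dataclass(frozen=True)
class MergerConfig:
    gap_mean: float = DEFAULT_GAP_MEAN
    gap_sd: float = DEFAULT_GAP_SD
    keep_threshold: int = DEFAULT_KEEP_THRESHOLD

    def __post_init__(self) -> None:
        if self.keep_threshold < 1:
            raise ValueError("keep_threshold must be >= 1")

    @property
    def similarity_margin(self) -> int:
        return compute_margin(self.gap_mean, self.gap_sd)


@dataclass
class Stretch:
    """A run of similar non-zero scores.

    ``pooled`` holds the non-zero scores of the constituent runs so merged
    heights can be recomputed as true medians rather than averaged heights.
    """

    interval: Interval
    direction: str
    height: float
    label: str = "delete"  # "keep" | "delete"
    pooled: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def size(self) -> int:
        return len(self.interval)

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.pooled.size == 0:
            object.__setattr__(
                self,
                "pooled",
                np.full(self.size, int(round(self.height)), dtype=np.int64),
            )


def _label(size: int, config: MergerConfig) -> str:
    return "keep" if size >= config.keep_threshold else "delete"


def build_stretches(track: ScoreTrack, config: MergerConfig = MergerConfig()) -> List[Stretch]:
    """Steps 1-2: maximal runs of equal non-zero score, labeled by size."""
    s = track.scores
    out: List[Stretch] = []
    if s.size == 0:
        return out
    change = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [s.size]))
    for a, b in zip(starts, ends):
        v = int(s[a])
        if v == 0:
            continue
        out.append(
            Stretch(
                interval=Interval(int(a), int(b)),
                direction=track.direction,
                height=float(v),
                label=_label(int(b - a), config),
                pooled=s[a:b].copy(),
            )
        )
    return out


def _check_sorted(stretches: List[Stretch]) -> None:
    for a, b in zip(stretches, stretches[1:]):
        if b.interval.start < a.interval.end:
            raise ValueError("stretches must be sorted and non-overlapping")
        if a.direction != b.direction:
            raise ValueError("stretches must share one direction")


def _mergeable(a: Stretch, b: Stretch, margin: int) -> bool:
    gap = b.interval.start - a.interval.end
    return abs(a.height - b.height) < margin and gap < margin


def _fuse(a: Stretch, b: Stretch, config: MergerConfig) -> Stretch:
    pooled = np.concatenate((a.pooled, b.pooled))
    iv = a.interval.hull(b.interval)
    return Stretch(
        interval=iv,
        direction=a.direction,
        height=float(np.median(pooled[pooled > 0])),
        label=_label(len(iv), config),
        pooled=pooled,
    )


def _merge_pass(stretches: List[Stretch], config: MergerConfig) -> List[Stretch]:
    """One left-to-right greedy scan, repeated to fixpoint by the caller."""
    margin = config.similarity_margin
    out: List[Stretch] = []
    for s in stretches:
        if out and _mergeable(out[-1], s, margin):
            out[-1] = _fuse(out[-1], s, config)
        else:
            out.append(s)
    return out


def _merge_fixpoint(stretches: List[Stretch], config: MergerConfig) -> List[Stretch]:
    while True:
        nxt = _merge_pass(stretches, config)
        if len(nxt) == len(stretches):
            return nxt
        stretches = nxt


def _remove_interruptive(stretches: List[Stretch], config: MergerConfig) -> List[Stretch]:
    """Step 4: drop delete stretches between two stretches that would merge."""
    margin = config.similarity_margin
    while True:
        removed = False
        for i in range(1, len(stretches) - 1):
            mid = stretches[i]
            if mid.label != "delete":
                continue
            left, right = stretches[i - 1], stretches[i + 1]
            gap = right.interval.start - left.interval.end
            if abs(left.height - right.height) < margin and gap < margin:
                del stretches[i]
                removed = True
                break
        if not removed:
            return stretches


def merge(stretches: List[Stretch], config: MergerConfig = MergerConfig()) -> List[Stretch]:
    """Steps 3-7 applied to sorted, non-overlapping same-direction stretches."""
    _check_sorted(stretches)
    work = list(stretches)
    work = _merge_fixpoint(work, config)                  # step 3
    work = _remove_interruptive(work, config)             # step 4
    work = _merge_fixpoint(work, config)                  # step 5
    work = [s for s in work if s.label == "keep"]         # step 6
    work = _merge_fixpoint(work, config)                  # step 7
    return work


def stretches_from_track(track: ScoreTrack, config: MergerConfig = MergerConfig()) -> List[Stretch]:
    """Full merger stage: build, label, and run the seven-step merge."""
    return merge(build_stretches(track, config), config)


def dump_stretches(stretches: List[Stretch], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tdirection\theight\tsize\tlabel\n")
        for s in stretches:
            fh.write(
                f"{s.interval.start}\t{s.interval.end}\t{s.direction}\t"
                f"{s.height:g}\t{s.size}\t{s.label}\n"
            )
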