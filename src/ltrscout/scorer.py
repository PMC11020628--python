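"""Bidirectional k-mer match-distance scoring.

Every k-mer is matched to its nearest identical copy downstream (forward
track) and upstream (backward track), independently.  A match only counts
when the distance between the two k-mer start positions lies inside a
[min_dist, max_dist] window; otherwise the score is 0.  Keeping the two
directions in separate tracks prevents nearby same-family elements from
fragmenting each other's score runs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kmers import kmer_codes

DEFAULT_K = 13
DEFAULT_MIN_DIST = 400
DEFAULT_MAX_DIST = 27_000


@dataclass(frozen=True)
class ScorerConfig:
    k: int = DEFAULT_K
    min_dist: int = DEFAULT_MIN_DIST
    max_dist: int = DEFAULT_MAX_DIST

    def __post_init__(self) -> None:
        if not 0 < self.k <= 31:
            raise ValueError("k must be in (0, 31]")
        if not 0 < self.min_dist < self.max_dist:
            raise ValueError("require 0 < min_dist < max_dist")


@dataclass
class ScoreTrack:
    sequence_id: str
    direction: str  # "forward" | "backward"
    scores: np.ndarray  # int64, one entry per k-mer start position

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")


def score(sequence: str, config: ScorerConfig = ScorerConfig(), sequence_id: str = "") -> tuple[ScoreTrack, ScoreTrack]:
    """Compute the forward and backward match-distance tracks for a sequence.

    Distances are measured between k-mer start positions: a k-mer at
    position 1,000 whose nearest in-window downstream copy starts at 2,000
    receives forward score 1,000, and the copy receives backward score
    1,000.
    """
    k, lo, hi = config.k, config.min_dist, config.max_dist
    if len(sequence) < k:
        warnings.warn(f"sequence {sequence_id!r} shorter than k={k}; empty tracks")
        empty = np.empty(0, dtype=np.int64)
        return (
            ScoreTrack(sequence_id, "forward", empty),
            ScoreTrack(sequence_id, "backward", empty.copy()),
        )
    codes = kmer_codes(sequence.upper(), k)
    n = codes.size
    fwd = np.zeros(n, dtype=np.int64)
    bwd = np.zeros(n, dtype=np.int64)

    valid = codes >= 0
    order = np.argsort(codes[valid], kind="stable")  # stable keeps positions sorted
    pos_sorted = np.flatnonzero(valid)[order]
    codes_sorted = codes[valid][order]
    # group boundaries of equal codes
    boundaries = np.flatnonzero(np.diff(codes_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [codes_sorted.size]))
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        p = pos_sorted[s:e]  # sorted positions of one repeated k-mer
        # forward: nearest downstream copy at distance >= lo
        j = np.searchsorted(p, p + lo, side="left")
        ok = j < p.size
        d = np.where(ok, p[np.minimum(j, p.size - 1)] - p, 0)
        fwd[p] = np.where(ok & (d <= hi), d, 0)
        # backward: nearest upstream copy at distance >= lo
        j = np.searchsorted(p, p - lo, side="right") - 1
        ok = j >= 0
        d = np.where(ok, p - p[np.maximum(j, 0)], 0)
        bwd[p] = np.where(ok & (d <= hi), d, 0)
    return (
        ScoreTrack(sequence_id, "forward", fwd),
        ScoreTrack(sequence_id, "backward", bwd),
    )


def score_brute_force(sequence: str, config: ScorerConfig = ScorerConfig(), sequence_id: str = "") -> tuple[ScoreTrack, ScoreTrack]:
    """O(n^2) reference scorer: scan all other positions for each k-mer.

    Kept as an independent oracle for the production scorer; used by tests
    and debug tooling only.
    """
    k, lo, hi = config.k, config.min_dist, config.max_dist
    codes = kmer_codes(sequence.upper(), k)
    n = codes.size
    fwd = np.zeros(n, dtype=np.int64)
    bwd = np.zeros(n, dtype=np.int64)
    for p in range(n):
        if codes[p] < 0:
            continue
        matches = np.flatnonzero(codes == codes[p])
        down = matches[(matches >= p + lo) & (matches <= p + hi)]
        if down.size:
            fwd[p] = down[0] - p
        up = matches[(matches <= p - lo) & (matches >= p - hi)]
        if up.size:
            bwd[p] = p - up[-1]
    return (
        ScoreTrack(sequence_id, "forward", fwd),
        ScoreTrack(sequence_id, "backward", bwd),
    )


def dump_tracks(fwd: ScoreTrack, bwd: ScoreTrack, path: str) -> None:
    """Wiggle-like TSV debug dump: position, forward, backward."""
    with open(path, "w") as fh:
        fh.write("position\tforward\tbackward\n")
        for i, (f, b) in enumerate(zip(fwd.scores, bwd.scores)):
            fh.write(f"{i}\t{f}\t{b}\n")
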