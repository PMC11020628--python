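"""Genome-wide repeat-content profiling.

Contract stand-in for a repeat detector that reports, per k-mer, how many
times above chance expectation the k-mer occurs: score =
max(0, observed/expected - 1), zero at or below expectation.  Expectation
comes from an order-2 Markov background fitted to the same genome(s);
cross-species mode fits and counts on the union of all input genomes.
An adapter reader accepts externally produced per-position score TSVs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._kmers import encode_bases, kmer_codes
from .intervals import Interval
from .sequence_io import GenomeSet

DEFAULT_PROFILE_K = 13
DEFAULT_JOIN_DISTANCE = 50
DEFAULT_MIN_REGION = 100
MARKOV_ORDER = 2


@dataclass
class RepeatProfile:
    k: int
    scores: Dict[str, np.ndarray] = field(default_factory=dict)
    regions: Dict[str, List[Interval]] = field(default_factory=dict)
    join_distance: int = DEFAULT_JOIN_DISTANCE
    min_region: int = DEFAULT_MIN_REGION

    def score_vector(self, sequence_id: str) -> np.ndarray:
        return self.scores[sequence_id]

    def add_sequence(self, sequence_id: str, scores: np.ndarray) -> None:
        self.scores[sequence_id] = scores
        self.regions[sequence_id] = repetitive_regions_from_scores(
            scores, self.join_distance, self.min_region
        )


def _markov_tables(genomes: GenomeSet, order: int) -> Tuple[np.ndarray, np.ndarray]:
    """(initial dinucleotide probabilities, order-2 transition probabilities).

    Transition table is indexed by context*4 + next_base with context =
    prev2*4 + prev1; add-one smoothing keeps probabilities positive.
    """
    ctx_counts = np.ones(4 ** order, dtype=np.float64)
    trans_counts = np.ones(4 ** (order + 1), dtype=np.float64)
    for _, seq in genomes.sequences:
        base = encode_bases(seq)
        n = base.size
        if n < order + 1:
            continue
        b0, b1, b2 = base[:-2], base[1:-1], base[2:]
        good = (b0 >= 0) & (b1 >= 0) & (b2 >= 0)
        ctx = b0[good] * 4 + b1[good]
        np.add.at(ctx_counts, ctx, 1)
        np.add.at(trans_counts, ctx * 4 + b2[good], 1)
    init = ctx_counts / ctx_counts.sum()
    trans = trans_counts.reshape(-1, 4)
    trans = trans / trans.sum(axis=1, keepdims=True)
    return init, trans.reshape(-1)


def _kmer_log_probs(codes: np.ndarray, k: int, init: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """log P(k-mer) under the order-2 background, per distinct code."""
    digits = np.empty((codes.size, k), dtype=np.int64)
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = c & 3
        c >>= 2
    logp = np.log(init[digits[:, 0] * 4 + digits[:, 1]])
    for j in range(2, k):
        ctx = digits[:, j - 2] * 4 + digits[:, j - 1]
        logp += np.log(trans[ctx * 4 + digits[:, j]])
    return logp


def train(genomes: GenomeSet, k: int = DEFAULT_PROFILE_K, join_distance: int = DEFAULT_JOIN_DISTANCE, min_region: int = DEFAULT_MIN_REGION) -> RepeatProfile:
    """Fit the background on the union of the genomes and score every position.

    Deterministic: counts and expectations are exact functions of the input.
    """
    total = genomes.total_length()
    if total < 100 * 4 ** MARKOV_ORDER:
        warnings.warn(
            f"genome too short ({total} bp) for an order-{MARKOV_ORDER} background; "
            "estimates will be noisy"
        )
    init, trans = _markov_tables(genomes, MARKOV_ORDER)

    per_seq_codes = {sid: kmer_codes(seq, k) for sid, seq in genomes.sequences}
    all_codes = np.concatenate([c[c >= 0] for c in per_seq_codes.values()]) if per_seq_codes else np.empty(0, dtype=np.int64)
    distinct, counts = np.unique(all_codes, return_counts=True)
    n_kmers = all_codes.size
    # one occurrence of any k-mer is always expected by chance in a de novo
    # assembly, so the expectation is floored at 1: unique sequence scores 0
    expected = np.maximum(
        1.0, n_kmers * np.exp(_kmer_log_probs(distinct, k, init, trans))
    )
    fold = np.maximum(0.0, counts / expected - 1.0)

    profile = RepeatProfile(k=k, join_distance=join_distance, min_region=min_region)
    for sid, codes in per_seq_codes.items():
        sc = np.zeros(codes.size, dtype=np.float64)
        valid = codes >= 0
        idx = np.searchsorted(distinct, codes[valid])
        sc[valid] = fold[idx]
        profile.add_sequence(sid, sc)
    return profile


def repetitive_regions_from_scores(scores: np.ndarray, join_distance: int = DEFAULT_JOIN_DISTANCE, min_region: int = DEFAULT_MIN_REGION) -> List[Interval]:
    """Maximal runs of positive score, gap-joined then length-filtered."""
    pos = np.flatnonzero(scores > 0)
    if pos.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > max(1, join_distance)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [pos.size]))
    regions = [Interval(int(pos[a]), int(pos[b - 1]) + 1) for a, b in zip(starts, ends)]
    return [r for r in regions if len(r) >= min_region]


def repetitive_regions(profile: RepeatProfile, sequence_id: str, min_len: Optional[int] = None) -> List[Interval]:
    if min_len is None:
        return profile.regions[sequence_id]
    return repetitive_regions_from_scores(
        profile.scores[sequence_id], profile.join_distance, min_len
    )


def repetitiveness_ratio(profile: RepeatProfile, sequence_id: str, interval: Interval) -> float:
    """Fraction of positions in the interval with a positive repeat score."""
    if len(interval) == 0:
        raise ValueError("empty interval")
    sc = profile.scores[sequence_id]
    lo = min(interval.start, sc.size)
    hi = min(interval.end, sc.size)
    nonzero = int(np.count_nonzero(sc[lo:hi] > 0))
    return nonzero / len(interval)


def read_score_tsv(path: str, sequence_id: str, length: int, k: int = DEFAULT_PROFILE_K) -> RepeatProfile:
    """Adapter: load externally produced (position, score) TSV as a profile."""
    sc = np.zeros(max(0, length - k + 1), dtype=np.float64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            p, v = line.split("\t")[:2]
            sc[int(p)] = float(v)
    profile = RepeatProfile(k=k)
    profile.add_sequence(sequence_id, sc)
    return profile
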