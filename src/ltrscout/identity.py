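"""Pairwise global identity scores.

The default estimator is exact: Needleman-Wunsch (match +1, mismatch -1,
gap -2) with identity = matches / alignment length.  Two operating modes
exist, "standard" (trusted range 80-100% identity) and "recent" (60-100%,
used for nested-element confirmation); the mode changes only the trusted
reporting range, not the arithmetic.  A fast k-mer estimator is available
as a drop-in; it must agree with the exact value within +/- 0.05 inside
the trusted range.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from ._kmers import kmer_codes


@dataclass(frozen=True)
class IdentityModel:
    mode: str = "standard"  # "standard" (80-100%) | "recent" (60-100%)
    k: int = 9
    use_fast_estimator: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "recent"):
            raise ValueError(f"unknown identity mode {self.mode!r}")

    @property
    def trusted_minimum(self) -> float:
        return 0.80 if self.mode == "standard" else 0.60


STANDARD = IdentityModel(mode="standard")
RECENT = IdentityModel(mode="recent")


@lru_cache(maxsize=1)
def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def exact_global_identity(a: str, b: str) -> float:
    """matches / alignment-length from one optimal global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _global_aligner().align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def kmer_identity_estimate(a: str, b: str, k: int = 9) -> float:
    """Fast alignment-free estimate from shared k-mer content.

    Jaccard-style containment mapped through the Poisson mutation model:
    identity ~= containment^(1/k).  Adequate inside the trusted ranges; the
    exact aligner remains the authority.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ca = kmer_codes(a.upper(), min(k, len(a)))
    cb = kmer_codes(b.upper(), min(k, len(b)))
    sa = set(ca[ca >= 0].tolist())
    sb = set(cb[cb >= 0].tolist())
    if not sa or not sb:
        return 0.0
    containment = len(sa & sb) / min(len(sa), len(sb))
    return containment ** (1.0 / k)


def global_identity(a: str, b: str, model: IdentityModel = STANDARD) -> float:
    """Identity of two sequences in [0, 1] under the given model."""
    if model.use_fast_estimator:
        return min(1.0, kmer_identity_estimate(a, b, model.k))
    return exact_global_identity(a, b)
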