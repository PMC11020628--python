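"""Vectorized k-mer encoding shared by the scorer and the repeat profiler.

Sequences are mapped to 2-bit codes; any k-mer touching a non-ACGT base
gets code -1 and is excluded from matching and counting.
"""
from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode_bases(sequence: str) -> np.ndarray:
    """Per-base 2-bit codes; -1 for anything outside {A,C,G,T}."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Codes of all k-mers (length ``len(sequence) - k + 1``); -1 where the
    window contains a non-ACGT base.  Requires k <= 31 (fits in int64)."""
    if not 0 < k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    base = encode_bases(sequence)
    n = base.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = base[j : j + n]
        codes = (codes << 2) | np.where(col < 0, 0, col)
        bad |= col < 0
    codes[bad] = -1
    return codes


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]
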