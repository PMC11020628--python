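"""Boundary sharpening before filtering.

k-mer extension: the 3' LTR grows by k-1 bp because the last score belongs
to the last k-mer, not the last nucleotide.  Missing-region extension: a
shorter LTR is tentatively grown forward and backward to the length of its
partner; each side's extension is kept only if the pairwise identity
strictly improves.
"""
from __future__ import annotations

import warnings
from .identity import STANDARD, IdentityModel, global_identity
from .intervals import Interval
from .matcher import ElementCandidate


def kmer_extend(element: ElementCandidate, k: int, sequence_length: int) -> ElementCandidate:
    """Extend the 3' LTR end by k-1 bp, clamped at the sequence end.

    The last score of a candidate is the score of its last k-mer, so the
    hull underestimates the end by k-1 bp.
    """
    end = element.ltr3.end + (k - 1)
    if end > sequence_length:
        warnings.warn("3' LTR extension clamped at sequence end")
        end = sequence_length
    element.ltr3 = Interval(element.ltr3.start, end)
    return element


def _nudge_ltr5_end(element: ElementCandidate, k: int) -> ElementCandidate:
    # the 5' LTR candidate end shares the k-mer-start hull geometry
    end5 = min(element.ltr5.end + (k - 1), element.ltr3.start)
    element.ltr5 = Interval(element.ltr5.start, end5)
    return element


def missing_region_extend(
    element: ElementCandidate,
    sequence: str,
    model: IdentityModel = STANDARD,
) -> ElementCandidate:
    """Grow the shorter LTR toward the longer one's length, keeping each
    side's extension only when identity between the paired LTRs improves."""
    len5, len3 = len(element.ltr5), len(element.ltr3)
    if len5 == len3:
        return element
    short_is_5 = len5 < len3
    short = element.ltr5 if short_is_5 else element.ltr3
    missing = abs(len3 - len5)

    def seq_of(iv: Interval) -> str:
        return sequence[iv.start : iv.end]

    def identity_with_partner(candidate_iv: Interval) -> float:
        a = seq_of(candidate_iv)
        b = seq_of(element.ltr3 if short_is_5 else element.ltr5)
        return global_identity(a, b, model)

    base_identity = identity_with_partner(short)
    best = short
    # backward (upstream) extension
    new_start = max(0, short.start - missing)
    if short_is_5 is False:
        # a 3' LTR cannot grow into the internal part past the 5' LTR end
        new_start = max(new_start, element.ltr5.end)
    cand = Interval(new_start, best.end)
    if new_start < short.start and identity_with_partner(cand) > base_identity:
        best = cand
        base_identity = identity_with_partner(best)
    # forward (downstream) extension, budget reduced by any backward gain
    remaining = missing - (len(best) - len(short))
    new_end = best.end + remaining
    if short_is_5:
        new_end = min(new_end, element.ltr3.start)
    else:
        new_end = min(new_end, len(sequence))
    cand = Interval(best.start, new_end)
    if new_end > best.end and identity_with_partner(cand) > base_identity:
        best = cand
    if short_is_5:
        element.ltr5 = best
    else:
        element.ltr3 = best
    return element


def extend(element: ElementCandidate, sequence: str, k: int, model: IdentityModel = STANDARD) -> ElementCandidate:
    element = kmer_extend(element, k, len(sequence))
    element = _nudge_ltr5_end(element, k)
    element = missing_region_extend(element, sequence, model)
    for child in element.children:
        extend(child, sequence, k, model)
    return element
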