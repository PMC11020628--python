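"""Evaluation protocol: reciprocal-overlap TP/FP, metrics, coverage.

A prediction is a true positive when it has 80% reciprocal overlap with a
truth element (>= 80% of each interval's own length), matched one-to-one
greedily by overlap.  A false positive requires both predicted LTRs to
reciprocally overlap two same-family entries of a dedicated false-positive
dataset.  Precision is computed over confirmed positives (TP + FP) only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .intervals import union_length
from .sequence_io import Annotation, GenomeSet

DEFAULT_RECIPROCAL = 0.8


def _overlap(a: Annotation, b: Annotation) -> int:
    if a.sequence_id != b.sequence_id:
        return 0
    return a.element_interval.overlap_length(b.element_interval)


def true_positives(
    predictions: Sequence[Annotation],
    truth: Sequence[Annotation],
    threshold: float = DEFAULT_RECIPROCAL,
) -> List[Tuple[int, int]]:
    """Greedy one-to-one matching; returns (prediction index, truth index)
    pairs, largest overlap first, ties to the leftmost prediction."""
    candidates: List[Tuple[int, int, int]] = []
    for i, p in enumerate(predictions):
        lp = len(p.element_interval)
        for j, t in enumerate(truth):
            ov = _overlap(p, t)
            if ov == 0:
                continue
            if ov >= threshold * lp and ov >= threshold * len(t.element_interval):
                candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], predictions[c[1]].element_interval.start, c[1]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched: List[Tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matched.append((i, j))
    return matched


def false_positives(
    predictions: Sequence[Annotation],
    fp_dataset: Sequence[Annotation],
    fp_families: Sequence[str],
    threshold: float = DEFAULT_RECIPROCAL,
) -> int:
    """Count predictions whose two LTRs each reciprocally overlap an entry
    of the false-positive dataset, with both entries from one family."""
    count = 0
    for p in predictions:
        if p.ltr5 is None or p.ltr3 is None:
            continue
        fams5: set[str] = set()
        fams3: set[str] = set()
        for entry, family in zip(fp_dataset, fp_families):
            if entry.sequence_id != p.sequence_id:
                continue
            for ltr, fams in ((p.ltr5, fams5), (p.ltr3, fams3)):
                ov = ltr.overlap_length(entry.element_interval)
                if ov >= threshold * len(ltr) and ov >= threshold * len(entry.element_interval):
                    fams.add(family)
        if fams5 & fams3:
            count += 1
    return count


@dataclass(frozen=True)
class Metrics:
    recall: float
    precision: float
    f1: float


def metrics(tp: int, fp: int, truth_count: int, prediction_count: int = 0) -> Metrics:
    """Recall = TP/GT; precision = TP/(TP+FP) over confirmed positives;
    F1 = harmonic mean; all 0 when undefined."""
    recall = tp / truth_count if truth_count else 0.0
    confirmed = tp + fp
    precision = tp / confirmed if confirmed else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return Metrics(recall=recall, precision=precision, f1=f1)


def coverage(
    annotations: Sequence[Annotation],
    genome: GenomeSet,
    nested_only: bool = False,
) -> float:
    """Fraction of the genome covered by the union of element intervals."""
    total = genome.total_length()
    if total == 0:
        return 0.0
    selected = [
        a
        for a in annotations
        if a.kind == "element" and (not nested_only or a.nesting_level >= 1)
    ]
    covered = 0
    for sid in genome.ids():
        covered += union_length(
            (a.element_interval.start, a.element_interval.end)
            for a in selected
            if a.sequence_id == sid
        )
    return covered / total


def evaluate(
    predictions: Sequence[Annotation],
    truth: Sequence[Annotation],
    fp_dataset: Optional[Sequence[Annotation]] = None,
    fp_families: Optional[Sequence[str]] = None,
    threshold: float = DEFAULT_RECIPROCAL,
) -> Dict[str, float]:
    matched = true_positives(predictions, truth, threshold)
    tp = len(matched)
    if fp_dataset is not None:
        fp = false_positives(predictions, fp_dataset, fp_families or [], threshold)
    else:
        # without a dedicated FP set, unmatched predictions count as FP
        fp = len(predictions) - tp
    m = metrics(tp, fp, len(truth), len(predictions))
    return {
        "tp": tp,
        "fp": fp,
        "truth": len(truth),
        "predictions": len(predictions),
        "recall": m.recall,
        "precision": m.precision,
        "f1": m.f1,
    }
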