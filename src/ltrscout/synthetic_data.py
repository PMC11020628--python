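"""Synthetic genomes with planted LTR-retrotransposons and exact truth.

The generator plants full elements (two near-identical LTRs flanking an
internal part that carries a polypurine tract, the whole insertion wrapped
in a target-site duplication), solo LTRs, nested insertions at arbitrary
depth, and MITE-pair decoys with terminal inverted repeats.  Same-family
insertions share a family consensus, so multi-copy families are genuinely
repetitive genome-wide.

Also implements the semi-synthetic transform used for classifier training:
extract the truth elements, randomly permute the residues of every
inter-element region, and reinsert the elements at their original
positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._kmers import reverse_complement
from .intervals import Interval
from .sequence_io import Annotation, GenomeSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_GC = 0.42
DEFAULT_SPACING = (28_000, 40_000)
_TIR_LENGTH = 20


@dataclass
class PlantSpec:
    """Blueprint for one planted family (or solo-LTR / MITE-decoy family)."""

    family_id: str
    ltr_length: int = 400
    internal_length: int = 1000
    ltr_divergence: float = 0.0
    family_divergence: float = 0.0
    copy_number: int = 1
    tsd_length: int = 5
    ppt_length: int = 15
    nesting: Optional["PlantSpec"] = None
    kind: str = "element"  # "element" | "solo_ltr" | "mite"
    indel_rate: float = 0.0
    gap_before: Optional[Tuple[int, int]] = None  # overrides the global spacing

    def __post_init__(self) -> None:
        if self.kind not in ("element", "solo_ltr", "mite"):
            raise ValueError(f"unknown spec kind {self.kind!r}")
        if self.ltr_length < 200:
            raise ValueError("ltr_length must be >= 200")
        if self.kind == "element" and self.internal_length < 200:
            raise ValueError("internal_length must be >= 200")
        for rate in (self.ltr_divergence, self.family_divergence):
            if not 0.0 <= rate <= 0.4:
                raise ValueError("divergence must lie in [0, 0.4]")
        if self.tsd_length < 4:
            raise ValueError("tsd_length must be >= 4")
        if self.ppt_length < 13:
            raise ValueError("ppt_length must be >= 13")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass
class PlantedPart:
    """One built insertion, coordinates relative to its own string."""

    seq: str
    kind: str
    family_id: str
    tsd_length: int
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    ppt: Optional[Interval] = None
    children: List["PlantedPart"] = field(default_factory=list)
    child_offsets: List[int] = field(default_factory=list)


@dataclass
class TruthSet:
    genome: GenomeSet
    annotations: List[Annotation]
    decoys: List[Annotation] = field(default_factory=list)


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode("ascii")


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    # replace with a uniformly random *different* base
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def _indel(seq: str, rate: float, rng: np.random.Generator, max_len: int = 60) -> str:
    if rate <= 0:
        return seq
    out: List[str] = []
    i = 0
    while i < len(seq):
        r = rng.random()
        if r < rate / 2:  # deletion
            i += int(rng.integers(1, max_len + 1))
        elif r < rate:  # insertion
            out.append(random_background(int(rng.integers(1, max_len + 1)), 0.5, rng))
            out.append(seq[i])
            i += 1
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def _make_ppt(length: int, rng: np.random.Generator) -> str:
    """Purine-rich run: >= 80% purines with strictly more A than G."""
    n_a = max(int(round(length * 0.6)), length - int(length * 0.4))
    n_g = max(1, int(round(length * 0.25)))
    n_py = length - n_a - n_g
    letters = ["A"] * n_a + ["G"] * n_g + ["T"] * max(0, n_py)
    rng.shuffle(letters)
    return "".join(letters)


@dataclass
class _FamilyConsensus:
    ltr: str
    pre: str = ""
    ppt: str = ""
    post: str = ""


class _Builder:
    def __init__(self, gc: float, rng: np.random.Generator) -> None:
        self.gc = gc
        self.rng = rng
        self.families: Dict[str, _FamilyConsensus] = {}

    def consensus(self, spec: PlantSpec) -> _FamilyConsensus:
        fam = self.families.get(spec.family_id)
        if fam is None:
            fam = _FamilyConsensus(ltr=random_background(spec.ltr_length, self.gc, self.rng))
            self.families[spec.family_id] = fam
        if spec.kind == "element" and not fam.ppt:
            post_len = min(50, max(5, spec.internal_length // 20))
            pre_len = spec.internal_length - spec.ppt_length - post_len
            fam.pre = random_background(pre_len, self.gc, self.rng)
            fam.ppt = _make_ppt(spec.ppt_length, self.rng)
            fam.post = random_background(post_len, self.gc, self.rng)
        return fam

    def build(self, spec: PlantSpec) -> PlantedPart:
        if spec.kind == "mite":
            return self._build_mite(spec)
        fam = self.consensus(spec)
        rng = self.rng
        ltr5 = _substitute(fam.ltr, spec.family_divergence, rng)
        if spec.kind == "solo_ltr":
            return PlantedPart(
                seq=ltr5,
                kind="solo_ltr",
                family_id=spec.family_id,
                tsd_length=spec.tsd_length,
            )
        ltr3 = _substitute(ltr5, spec.ltr_divergence, rng)
        if spec.indel_rate > 0:
            ltr3 = _indel(ltr3, spec.indel_rate, rng)
        pre = _substitute(fam.pre, spec.family_divergence, rng)
        post = _substitute(fam.post, spec.family_divergence, rng)
        ppt = fam.ppt  # untouched so the purine signature is guaranteed
        l5 = len(ltr5)
        internal = pre + ppt + post
        part = PlantedPart(
            seq=ltr5 + internal + ltr3,
            kind="element",
            family_id=spec.family_id,
            tsd_length=spec.tsd_length,
            ltr5=Interval(0, l5),
            ltr3=Interval(l5 + len(internal), l5 + len(internal) + len(ltr3)),
            ppt=Interval(l5 + len(pre), l5 + len(pre) + len(ppt)),
        )
        if spec.nesting is not None:
            part = self._nest(part, spec.nesting)
        return part

    def _nest(self, parent: PlantedPart, child_spec: PlantSpec) -> PlantedPart:
        child = self.build(child_spec)
        rng = self.rng
        t = child_spec.tsd_length
        # insert inside the parent's internal part, clear of the PPT
        lo = parent.ltr5.end + 100
        hi = parent.ppt.start - 100 - t
        if hi <= lo:
            raise ValueError(
                f"internal part of family {parent.family_id!r} too small to nest into"
            )
        at = int(rng.integers(lo, hi))
        seq = parent.seq
        grown = seq[: at + t] + child.seq + seq[at:]
        added = len(child.seq) + t
        part = PlantedPart(
            seq=grown,
            kind=parent.kind,
            family_id=parent.family_id,
            tsd_length=parent.tsd_length,
            ltr5=parent.ltr5,
            ltr3=parent.ltr3.shift(added),
            ppt=parent.ppt.shift(added),
            children=parent.children + [child],
            child_offsets=parent.child_offsets + [at + t],
        )
        return part

    def _build_mite(self, spec: PlantSpec) -> PlantedPart:
        fam = self.families.get(spec.family_id)
        rng = self.rng
        if fam is None:
            tir = random_background(_TIR_LENGTH, self.gc, rng)
            core = random_background(spec.ltr_length - 2 * _TIR_LENGTH, self.gc, rng)
            mite = tir + core + reverse_complement(tir)
            spacer_core = random_background(max(0, spec.internal_length - 25), self.gc, rng)
            # purine run near the spacer end so only the TIR test rejects it
            spacer = spacer_core + _make_ppt(15, rng) + random_background(10, self.gc, rng)
            fam = _FamilyConsensus(ltr=mite, pre=spacer)
            self.families[spec.family_id] = fam
        copy1 = _substitute(fam.ltr, spec.family_divergence, rng)
        copy2 = _substitute(copy1, spec.ltr_divergence, rng)
        spacer = _substitute(fam.pre, spec.family_divergence, rng)
        l1 = len(copy1)
        return PlantedPart(
            seq=copy1 + spacer + copy2,
            kind="mite",
            family_id=spec.family_id,
            tsd_length=spec.tsd_length,
            ltr5=Interval(0, l1),
            ltr3=Interval(l1 + len(spacer), l1 + len(spacer) + len(copy2)),
        )


def _emit_annotations(part: PlantedPart, offset: int, sequence_id: str, name: str, level: int, out: List[Annotation], parent_name: str = "") -> None:
    ann = Annotation(
        sequence_id=sequence_id,
        element_interval=Interval(offset, offset + len(part.seq)),
        ltr5=part.ltr5.shift(offset) if part.ltr5 else None,
        ltr3=part.ltr3.shift(offset) if part.ltr3 else None,
        ppt=part.ppt.shift(offset) if part.ppt else None,
        nesting_level=level,
        kind="element" if part.kind in ("element", "mite") else "solo_ltr",
        name=name,
        parent=parent_name,
    )
    out.append(ann)
    for i, (child, child_at) in enumerate(zip(part.children, part.child_offsets)):
        start = offset + child_at
        child_idx = len(out)
        _emit_annotations(child, start, sequence_id, f"{name}.n{i}", level + 1, out, name)
        t = child.tsd_length
        out[child_idx].tsd = (
            Interval(start - t, start),
            Interval(start + len(child.seq), start + len(child.seq) + t),
        )


def generate_genome(
    specs: List[PlantSpec],
    background_length: int,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    spacing: Tuple[int, int] = DEFAULT_SPACING,
    sequence_id: str = "synth1",
) -> TruthSet:
    """Plant every spec copy into an i.i.d. background; deterministic per seed."""
    rng = np.random.default_rng(seed)
    builder = _Builder(gc, rng)

    insertions: List[Tuple[PlantSpec, PlantedPart]] = []
    for spec in specs:
        for _ in range(spec.copy_number):
            insertions.append((spec, builder.build(spec)))

    host = random_background(background_length, gc, rng)
    # pick insertion points left to right with the requested gaps
    points: List[int] = []
    cursor = 1000
    for spec, _ in insertions:
        lo, hi = spec.gap_before or spacing
        cursor += int(rng.integers(lo, hi + 1))
        points.append(cursor)
    if points and points[-1] + 1000 > background_length:
        raise ValueError(
            f"insertions overflow background: need > {points[-1] + 1000} bp, "
            f"have {background_length}"
        )

    parts: List[str] = []
    out_len = 0
    cursor = 0
    annotations: List[Annotation] = []
    decoys: List[Annotation] = []
    counters: Dict[str, int] = {}
    for (spec, built), at in zip(insertions, points):
        t = spec.tsd_length
        parts.append(host[cursor : at + t])
        out_len += at + t - cursor
        elem_start = out_len
        parts.append(built.seq)
        out_len += len(built.seq)
        cursor = at  # replays host[at:at+t] as the right-flank TSD copy
        idx = counters.get(spec.family_id, 0)
        counters[spec.family_id] = idx + 1
        name = f"{spec.family_id}_{idx}"
        sink: List[Annotation] = []
        _emit_annotations(built, elem_start, sequence_id, name, 0, sink)
        sink[0].tsd = (
            Interval(elem_start - t, elem_start),
            Interval(out_len, out_len + t),
        )
        if built.kind == "mite":
            decoys.extend(sink)
        else:
            annotations.extend(sink)
    parts.append(host[cursor:])
    genome = GenomeSet()
    genome.add(sequence_id, "".join(parts), "synthetic")
    return TruthSet(genome=genome, annotations=annotations, decoys=decoys)


def demo_specs() -> List[PlantSpec]:
    """A plant-genome-like showcase layout: 17 elements and 3 solo LTRs
    across three families, with two one-level nests, one two-level nest,
    and MITE-pair decoys.  Pairs with a ~1 Mb background."""
    famA = dict(family_id="famA", ltr_length=400, internal_length=1500,
                ltr_divergence=0.02, family_divergence=0.02)
    famB = dict(family_id="famB", ltr_length=600, internal_length=2500,
                ltr_divergence=0.03, family_divergence=0.03)
    famC = dict(family_id="famC", ltr_length=400, internal_length=1200,
                ltr_divergence=0.04, family_divergence=0.03)
    # nested copies are *recent* insertions: low divergence by definition
    recent_b = {**famB, "ltr_divergence": 0.015, "family_divergence": 0.015}
    recent_c = {**famC, "ltr_divergence": 0.015, "family_divergence": 0.015}
    nest_b = PlantSpec(**recent_b, nesting=PlantSpec(**recent_b))
    nest_c = PlantSpec(**recent_c, nesting=PlantSpec(**recent_c))
    deep_c = PlantSpec(
        **recent_c, nesting=PlantSpec(**recent_c, nesting=PlantSpec(**recent_c))
    )
    return [
        PlantSpec(**famA, copy_number=3),
        PlantSpec(family_id="famA", kind="solo_ltr", ltr_length=400,
                  gap_before=(3000, 7000)),
        PlantSpec(**famA, copy_number=3),
        PlantSpec(**famB, copy_number=2),
        PlantSpec(family_id="famB", kind="solo_ltr", ltr_length=600,
                  gap_before=(3000, 7000)),
        PlantSpec(**famB, copy_number=2),
        nest_b,
        nest_c,
        PlantSpec(family_id="famC", kind="solo_ltr", ltr_length=400,
                  gap_before=(3000, 7000)),
        deep_c,
        PlantSpec(family_id="famM", kind="mite", ltr_length=300,
                  internal_length=900, copy_number=3),
    ]


def demo_genome(seed: int = 0, background_length: int = 1_000_000) -> TruthSet:
    """Deterministic 1 Mb-scale genome built from :func:`demo_specs`."""
    return generate_genome(demo_specs(), background_length, seed=seed)


def make_semisynthetic(genome: GenomeSet, truth: List[Annotation], seed: int = 0) -> GenomeSet:
    """Shuffle (permute residues of) every inter-element region, keeping the
    truth elements byte-identical at their original positions."""
    rng = np.random.default_rng(seed)
    out = GenomeSet()
    by_seq: Dict[str, List[Annotation]] = {}
    for a in truth:
        by_seq.setdefault(a.sequence_id, []).append(a)
    for sid, seq in genome.sequences:
        top = [a for a in by_seq.get(sid, []) if a.nesting_level == 0]
        top.sort(key=lambda a: a.element_interval.start)
        for a, b in zip(top, top[1:]):
            if a.element_interval.overlaps(b.element_interval):
                raise ValueError(
                    f"overlapping truth intervals without declared nesting: "
                    f"{a.name or a.element_interval} / {b.name or b.element_interval}"
                )
        pieces: List[str] = []
        cursor = 0
        for a in top:
            iv = a.element_interval
            pieces.append(_permute(seq[cursor : iv.start], rng))
            pieces.append(seq[iv.start : iv.end])
            cursor = iv.end
        pieces.append(_permute(seq[cursor:], rng))
        out.add(sid, "".join(pieces), genome.source_labels[sid])
    return out


def _permute(segment: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    return arr[rng.permutation(arr.size)].tobytes().decode("ascii")
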