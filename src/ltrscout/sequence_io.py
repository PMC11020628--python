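"""Genome input and annotation output.

FASTA reading is delegated to Biopython; annotations are written as BED
(0-based half-open) or GFF3 (1-based inclusive) with PPT/TSD child features
and Parent references for nested elements.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .intervals import Interval

_IUPAC = set("ACGTNRYSWKMBDHV")


@dataclass
class GenomeSet:
    """Ordered collection of uppercased sequences with a genome-of-origin tag."""

    sequences: List[Tuple[str, str]] = field(default_factory=list)
    source_labels: Dict[str, str] = field(default_factory=dict)

    def add(self, seq_id: str, residues: str, source: str) -> None:
        if seq_id in self.source_labels:
            raise ValueError(f"duplicate sequence identifier: {seq_id!r}")
        if not residues:
            raise ValueError(f"empty sequence for record {seq_id!r}")
        residues = residues.upper()
        bad = set(residues) - _IUPAC
        if bad:
            raise ValueError(
                f"record {seq_id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        self.sequences.append((seq_id, residues))
        self.source_labels[seq_id] = source

    def ids(self) -> List[str]:
        return [sid for sid, _ in self.sequences]

    def get(self, seq_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class Annotation:
    """One reported feature: a full element, a solo LTR, or a complex region."""

    sequence_id: str
    element_interval: Interval
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    ppt: Optional[Interval] = None
    ppt_reversed: bool = False
    tsd: Optional[Tuple[Interval, Interval]] = None
    nesting_level: int = 0
    kind: str = "element"
    name: str = ""
    parent: str = ""
    shared_ltr_group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("element", "solo_ltr", "complex_region"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if len(self.element_interval) == 0:
            raise ValueError("empty element interval")
        if self.ltr5 is not None and self.ltr3 is not None:
            if not (self.ltr5.start < self.ltr3.start):
                raise ValueError("5' LTR must precede 3' LTR")
            for ltr in (self.ltr5, self.ltr3):
                if not self.element_interval.contains_interval(ltr):
                    raise ValueError("LTR outside element interval")
        elif self.kind == "element" and (self.ltr5 is None) != (self.ltr3 is None):
            raise ValueError("element annotation needs both LTRs or neither")

    @property
    def internal(self) -> Optional[Interval]:
        if self.ltr5 is None or self.ltr3 is None:
            return None
        return Interval(self.ltr5.end, self.ltr3.start)


def read_fasta(paths: Sequence[str]) -> GenomeSet:
    """Load one or more FASTA files into a single GenomeSet.

    The source label of every record is the basename of the file it came
    from, so cross-species runs keep genome-of-origin information.
    """
    gs = GenomeSet()
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        label = os.path.basename(path)
        n_before = len(gs)
        for rec in SeqIO.parse(path, "fasta"):
            gs.add(rec.id, str(rec.seq), label)
        if len(gs) == n_before:
            raise ValueError(f"no FASTA records found in {path}")
    return gs


def write_fasta(genomes: GenomeSet, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in genomes.sequences:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _bed_row(a: Annotation, idx: int) -> str:
    name = a.name or f"{a.kind}_{idx}"
    extras = [
        a.kind,
        str(a.nesting_level),
        f"{a.ltr5.start}-{a.ltr5.end}" if a.ltr5 else ".",
        f"{a.ltr3.start}-{a.ltr3.end}" if a.ltr3 else ".",
        (f"{a.ppt.start}-{a.ppt.end}" + ("(rev)" if a.ppt_reversed else ""))
        if a.ppt
        else ".",
        f"{a.tsd[0].start}-{a.tsd[0].end},{a.tsd[1].start}-{a.tsd[1].end}"
        if a.tsd
        else ".",
        a.parent or ".",
        a.shared_ltr_group or ".",
    ]
    return "\t".join(
        [a.sequence_id, str(a.element_interval.start), str(a.element_interval.end), name]
        + extras
    )


_KIND_TO_SO = {
    "element": "LTR_retrotransposon",
    "solo_ltr": "solo_LTR",
    "complex_region": "repeat_region",
}


def _gff_rows(a: Annotation, idx: int) -> List[str]:
    name = a.name or f"{a.kind}_{idx}"
    rows = []

    def row(ftype: str, iv: Interval, attrs: str) -> str:
        return "\t".join(
            [
                a.sequence_id,
                "ltrscout",
                ftype,
                str(iv.start + 1),
                str(iv.end),
                ".",
                "+",
                ".",
                attrs,
            ]
        )

    attrs = f"ID={name};nesting_level={a.nesting_level}"
    if a.parent:
        attrs += f";Parent={a.parent}"
    if a.shared_ltr_group:
        attrs += f";shared_ltr_group={a.shared_ltr_group}"
    rows.append(row(_KIND_TO_SO[a.kind], a.element_interval, attrs))
    if a.ltr5:
        rows.append(row("long_terminal_repeat", a.ltr5, f"ID={name}.ltr5;Parent={name}"))
    if a.ltr3:
        rows.append(row("long_terminal_repeat", a.ltr3, f"ID={name}.ltr3;Parent={name}"))
    if a.ppt:
        strand_note = ";orientation=reversed" if a.ppt_reversed else ""
        rows.append(row("RR_tract", a.ppt, f"ID={name}.ppt;Parent={name}{strand_note}"))
    if a.tsd:
        rows.append(row("target_site_duplication", a.tsd[0], f"ID={name}.tsd5;Parent={name}"))
        rows.append(row("target_site_duplication", a.tsd[1], f"ID={name}.tsd3;Parent={name}"))
    return rows


def write_annotations(annotations: Sequence[Annotation], path: str, format: str = "bed") -> None:
    """Write annotations as BED (0-based half-open) or GFF3 (1-based inclusive)."""
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for i, a in enumerate(annotations):
                for line in _gff_rows(a, i):
                    fh.write(line + "\n")
        else:
            for i, a in enumerate(annotations):
                fh.write(_bed_row(a, i) + "\n")


def _parse_iv(token: str) -> Optional[Interval]:
    if token == ".":
        return None
    token = token.replace("(rev)", "")
    s, e = token.split("-")
    return Interval(int(s), int(e))


def read_annotations(path: str) -> List[Annotation]:
    """Read the BED dialect produced by :func:`write_annotations`.

    Plain 3+ column BED is accepted too; missing columns default sensibly.
    """
    out: List[Annotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            iv = Interval(int(f[1]), int(f[2]))
            ann = Annotation(
                sequence_id=f[0],
                element_interval=iv,
                name=f[3] if len(f) > 3 else "",
                kind=f[4] if len(f) > 4 else "element",
                nesting_level=int(f[5]) if len(f) > 5 else 0,
                ltr5=_parse_iv(f[6]) if len(f) > 6 else None,
                ltr3=_parse_iv(f[7]) if len(f) > 7 else None,
                ppt=_parse_iv(f[8]) if len(f) > 8 else None,
                ppt_reversed=len(f) > 8 and "(rev)" in f[8],
                tsd=(
                    tuple(_parse_iv(t) for t in f[9].split(","))  # type: ignore[arg-type]
                    if len(f) > 9 and f[9] != "."
                    else None
                ),
                parent=f[10] if len(f) > 10 and f[10] != "." else "",
                shared_ltr_group=f[11] if len(f) > 11 and f[11] != "." else "",
            )
            out.append(ann)
    return out
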