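"""End-to-end detection: scorer -> merger -> detector -> matcher ->
extender -> filters -> TSD post-processing, per input sequence, with the
repeat profile trained once on the union of all input genomes."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files as _pkg_files
from typing import Dict, List, Optional, Sequence, Tuple

from . import detector, extender, filter_postprocess, matcher, merger, repeat_profile, scorer
from .detector import MergeModel
from .filter_postprocess import FilterConfig
from .intervals import Interval, reciprocal_overlap
from .matcher import ElementCandidate, MatcherConfig
from .merger import MergerConfig
from .scorer import ScorerConfig
from .sequence_io import Annotation, GenomeSet

log = logging.getLogger("ltrscout")


@dataclass
class PipelineConfig:
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    merger: MergerConfig = field(default_factory=MergerConfig)
    matcher: MatcherConfig = field(default_factory=MatcherConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    profile_k: int = repeat_profile.DEFAULT_PROFILE_K


def default_model() -> MergeModel:
    """The packaged pair-merge model, trained on shipped synthetic fixtures."""
    path = _pkg_files("ltrscout").joinpath("data/default_model.json")
    return MergeModel.load(str(path))


def _flatten(elements: Sequence[ElementCandidate]) -> List[ElementCandidate]:
    out: List[ElementCandidate] = []
    for e in elements:
        out.append(e)
        out.extend(_flatten(e.children))
    return out


def _shared_ltr_groups(elements: List[ElementCandidate]) -> Dict[int, str]:
    """Label groups of surviving elements that share an LTR."""
    parent = list(range(len(elements)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(elements):
        for j in range(i + 1, len(elements)):
            b = elements[j]
            for la in (a.ltr5, a.ltr3):
                for lb in (b.ltr5, b.ltr3):
                    if reciprocal_overlap(la, lb, 0.8):
                        parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(len(elements)):
        groups.setdefault(find(i), []).append(i)
    labels: Dict[int, str] = {}
    n = 0
    for members in groups.values():
        if len(members) > 1:
            n += 1
            for m in members:
                labels[m] = f"G{n}"
    return labels


def _drop_contained_strays(survivors: List[ElementCandidate]) -> List[ElementCandidate]:
    """Drop an element lying strictly inside another survivor that does not
    declare it as a nested child: such containment without nesting can only
    be a slice artifact of the containing element."""
    descendants: Dict[int, set] = {}

    def collect(e: ElementCandidate) -> set:
        out = set()
        for c in e.children:
            out.add(id(c))
            out |= collect(c)
        return out

    for e in survivors:
        descendants[id(e)] = collect(e)
    keep = []
    for e in survivors:
        stray = any(
            f is not e
            and len(f.span) > len(e.span)
            and f.span.contains_interval(e.span)
            and id(e) not in descendants[id(f)]
            for f in survivors
        )
        if not stray:
            keep.append(e)
    return keep


def detect(
    genomes: GenomeSet,
    model: Optional[MergeModel] = None,
    config: Optional[PipelineConfig] = None,
) -> List[Annotation]:
    """Annotate LTR-retrotransposons in every sequence of the genome set."""
    config = config or PipelineConfig()
    model = model or default_model()
    profile = repeat_profile.train(genomes, k=config.profile_k)
    annotations: List[Annotation] = []
    for sid, seq in genomes.sequences:
        annotations.extend(
            _detect_sequence(sid, seq, profile, model, config)
        )
    return annotations


def _detect_sequence(
    sid: str,
    seq: str,
    profile: repeat_profile.RepeatProfile,
    model: MergeModel,
    config: PipelineConfig,
) -> List[Annotation]:
    fwd_track, bwd_track = scorer.score(seq, config.scorer, sid)
    fwd_stretches = merger.stretches_from_track(fwd_track, config.merger)
    bwd_stretches = merger.stretches_from_track(bwd_track, config.merger)
    log.info(
        "%s: %d forward / %d backward stretches",
        sid, len(fwd_stretches), len(bwd_stretches),
    )
    fwd_cands = detector.assemble_candidates(fwd_stretches, model, profile, sid)
    bwd_cands = detector.assemble_candidates(bwd_stretches, model, profile, sid)
    log.info("%s: %d forward / %d backward candidates", sid, len(fwd_cands), len(bwd_cands))
    elements, solos, complexes = matcher.match_candidates(
        seq,
        sid,
        fwd_cands,
        bwd_cands,
        fwd_track,
        bwd_track,
        profile,
        model,
        config.scorer,
        config.merger,
        config.matcher,
    )
    log.info(
        "%s: matcher emitted %d elements, %d solos, %d complex regions",
        sid, len(elements), len(solos), len(complexes),
    )

    for e in elements:
        extender.extend(e, seq, config.scorer.k)

    flat = _flatten(elements)
    survivors: List[ElementCandidate] = []
    ppt_hits: Dict[int, Tuple[Interval, bool]] = {}
    for e in flat:
        ok, ppt = filter_postprocess.filter_element(e, seq, config.filter)
        if ok:
            ppt_hits[id(e)] = ppt
            survivors.append(e)
    survivors = _drop_contained_strays(survivors)
    solos_kept = filter_postprocess.drop_orphan_solos(solos, survivors)
    log.info("%s: %d elements, %d solos survive filtering", sid, len(survivors), len(solos_kept))

    tsds: Dict[int, Tuple[Interval, Interval]] = {}
    for e in survivors:
        tsd = filter_postprocess.find_tsd(e, seq, config.filter)
        if tsd is not None:
            tsds[id(e)] = tsd

    # nesting levels and parents from containment among survivors
    order = sorted(range(len(survivors)), key=lambda i: -len(survivors[i].span))
    names = {}
    for rank, i in enumerate(order):
        names[id(survivors[i])] = f"{sid}.e{rank}"
    group_labels = _shared_ltr_groups(survivors)

    out: List[Annotation] = []
    for i, e in enumerate(survivors):
        containers = [
            f
            for f in survivors
            if f is not e
            and f.span.contains_interval(e.span)
            and len(f.span) > len(e.span)
        ]
        level = len(containers)
        parent_name = ""
        if containers:
            nearest = min(containers, key=lambda f: len(f.span))
            parent_name = names[id(nearest)]
        ppt, ppt_rev = ppt_hits[id(e)]
        out.append(
            Annotation(
                sequence_id=sid,
                element_interval=e.span,
                ltr5=e.ltr5,
                ltr3=e.ltr3,
                ppt=ppt,
                ppt_reversed=ppt_rev,
                tsd=tsds.get(id(e)),
                nesting_level=level,
                kind="element",
                name=names[id(e)],
                parent=parent_name,
                shared_ltr_group=group_labels.get(i, ""),
            )
        )
    for j, s in enumerate(solos_kept):
        out.append(
            Annotation(
                sequence_id=sid,
                element_interval=s.interval,
                kind="solo_ltr",
                name=f"{sid}.s{j}",
            )
        )
    for j, c in enumerate(complexes):
        out.append(
            Annotation(
                sequence_id=sid,
                element_interval=c.interval,
                kind="complex_region",
                name=f"{sid}.c{j}",
            )
        )
    out.sort(key=lambda a: a.element_interval.start)
    return out
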