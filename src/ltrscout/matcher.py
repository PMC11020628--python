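"""Matching candidate LTRs into elements via a directed-weighted graph.

Forward candidates point downstream, backward candidates upstream; an edge
is added from a candidate to the opposite-direction candidate containing
the positions its scores indicate, weighted by the fraction of the source's
k-mers that have an exact copy in the target.  Overlapping forward/backward
candidates are joined by unweighted vertical connections.  Connected
components are resolved case by case: single elements, solo LTRs, recently
nested elements (with recursive splicing for deeper nests), and complex
regions of sequential same-family insertions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from ._kmers import kmer_codes
from .detector import LtrCandidate, MergeModel, assemble_candidates
from .identity import RECENT, STANDARD, IdentityModel, global_identity, kmer_identity_estimate
from .intervals import Interval, subtract
from .merger import MergerConfig, stretches_from_track
from .repeat_profile import RepeatProfile
from .scorer import ScoreTrack, ScorerConfig, score

_ALIGN_CELL_CAP = 16_000_000  # fall back to the k-mer estimator above this


@dataclass(frozen=True)
class MatcherConfig:
    min_edge_weight: float = 0.27
    min_internal_ratio: float = 0.33
    nested_min_identity: float = 0.60
    complex_min_identity: float = 0.80
    trim_ratio: float = 0.5
    recursion_depth: int = 5

    def __post_init__(self) -> None:
        for v in (
            self.min_edge_weight,
            self.min_internal_ratio,
            self.nested_min_identity,
            self.complex_min_identity,
            self.trim_ratio,
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("matcher thresholds must lie in [0, 1]")


@dataclass
class Node:
    node_id: int
    direction: str  # "forward" | "backward"
    interval: Interval
    candidate: LtrCandidate


@dataclass
class ElementCandidate:
    ltr5: Interval
    ltr3: Interval
    case_origin: str  # single | solo | recently_nested | complex | deeply_nested
    weights: Tuple[float, float] = (0.0, 0.0)
    children: List["ElementCandidate"] = field(default_factory=list)
    component_id: int = -1

    @property
    def internal(self) -> Interval:
        return Interval(self.ltr5.end, self.ltr3.start)

    @property
    def span(self) -> Interval:
        return Interval(self.ltr5.start, self.ltr3.end)


@dataclass
class SoloCandidate:
    interval: Interval
    component_id: int


@dataclass
class ComplexRegion:
    interval: Interval
    component_id: int


class MatchGraph:
    """Directed weighted edges between opposite-direction candidates, plus
    unweighted vertical connections between overlapping candidates."""

    def __init__(self) -> None:
        self.nodes: Dict[int, Node] = {}
        self.weights: Dict[Tuple[int, int], float] = {}
        self.vertical: set[frozenset] = set()

    def add_node(self, node: Node) -> None:
        self.nodes[node.node_id] = node

    def add_edge(self, src: int, dst: int, weight: float) -> None:
        if self.nodes[src].direction == self.nodes[dst].direction:
            raise ValueError("edges connect opposite-direction candidates only")
        self.weights[(src, dst)] = weight

    def add_vertical(self, a: int, b: int) -> None:
        if not self.nodes[a].interval.overlaps(self.nodes[b].interval):
            raise ValueError("vertical connections join overlapping nodes only")
        self.vertical.add(frozenset((a, b)))

    def weight(self, src: int, dst: int) -> float:
        return self.weights.get((src, dst), 0.0)

    def components(self) -> List[List[int]]:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((u, v) for u, v in self.weights)
        g.add_edges_from(tuple(pair) for pair in self.vertical)
        return [sorted(c) for c in nx.connected_components(g)]

    def mutual_pairs(self, nodes: Sequence[int]) -> List[Tuple[int, int]]:
        """(forward, backward) node pairs with edges both ways, 5' first."""
        out = []
        for f in nodes:
            if self.nodes[f].direction != "forward":
                continue
            for b in nodes:
                if self.nodes[b].direction != "backward":
                    continue
                if (f, b) in self.weights and (b, f) in self.weights:
                    if self.nodes[f].interval.start < self.nodes[b].interval.start:
                        out.append((f, b))
        return out


def _kmer_position_codes(sequence: str, interval: Interval, k: int) -> np.ndarray:
    sub = sequence[interval.start : interval.end]
    codes = kmer_codes(sub, k)
    return codes[codes >= 0]


def edge_weight(sequence: str, source: Interval, target: Interval, k: int) -> float:
    """Fraction of the source's k-mers with an exact copy in the target."""
    src = _kmer_position_codes(sequence, source, k)
    if src.size == 0:
        return 0.0
    tgt = set(_kmer_position_codes(sequence, target, k).tolist())
    hits = sum(1 for c in src.tolist() if c in tgt)
    return hits / src.size


def build_graph(
    fwd: Sequence[LtrCandidate],
    bwd: Sequence[LtrCandidate],
    fwd_track: ScoreTrack,
    bwd_track: ScoreTrack,
    sequence: str,
    k: int,
) -> MatchGraph:
    graph = MatchGraph()
    nodes: List[Node] = []
    for cand in fwd:
        nodes.append(Node(len(nodes), "forward", cand.interval, cand))
    for cand in bwd:
        nodes.append(Node(len(nodes), "backward", cand.interval, cand))
    for n in nodes:
        graph.add_node(n)

    fwd_nodes = [n for n in nodes if n.direction == "forward"]
    bwd_nodes = [n for n in nodes if n.direction == "backward"]

    def targets_of(node: Node, track: ScoreTrack, sign: int) -> np.ndarray:
        lo = node.interval.start
        hi = min(node.interval.end, track.scores.size)
        if hi <= lo:
            return np.empty(0, dtype=np.int64)
        s = track.scores[lo:hi]
        pos = np.arange(lo, hi, dtype=np.int64)
        nz = s > 0
        return pos[nz] + sign * s[nz]

    def connect(sources: List[Node], sinks: List[Node], track: ScoreTrack, sign: int) -> None:
        if not sinks:
            return
        starts = np.array([n.interval.start for n in sinks], dtype=np.int64)
        ends = np.array([n.interval.end for n in sinks], dtype=np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        sink_ids = np.array([sinks[i].node_id for i in order], dtype=np.int64)
        for node in sources:
            t = targets_of(node, track, sign)
            if t.size == 0:
                continue
            idx = np.searchsorted(starts, t, side="right") - 1
            ok = (idx >= 0) & (t < ends[np.maximum(idx, 0)])
            for sid in np.unique(sink_ids[idx[ok]]):
                dst = int(sid)
                w = edge_weight(sequence, node.interval, graph.nodes[dst].interval, k)
                graph.add_edge(node.node_id, dst, w)

    connect(fwd_nodes, bwd_nodes, fwd_track, +1)
    connect(bwd_nodes, fwd_nodes, bwd_track, -1)

    for f in fwd_nodes:
        for b in bwd_nodes:
            if f.interval.overlaps(b.interval):
                graph.add_vertical(f.node_id, b.node_id)
    return graph


def trim_hyperextension(
    graph: MatchGraph,
    sequence: str,
    k: int,
    config: MatcherConfig = MatcherConfig(),
) -> MatchGraph:
    """Repair wrongly fused candidates revealed by asymmetric edge weights.

    For a mutual pair whose weights are strongly asymmetric, the source of
    the low-weight edge is trimmed to the hull of its positions whose
    k-mers match the partner, then both weights are recomputed.
    """
    pairs = {
        frozenset((u, v))
        for (u, v) in graph.weights
        if (v, u) in graph.weights
    }
    for pair in pairs:
        u, v = tuple(pair)
        w_uv, w_vu = graph.weight(u, v), graph.weight(v, u)
        if w_uv > w_vu:
            u, v = v, u
            w_uv, w_vu = w_vu, w_uv
        # now u is the low-weight source
        if w_vu <= 0 or w_uv / w_vu >= config.trim_ratio:
            continue
        node = graph.nodes[u]
        partner = graph.nodes[v]
        # hyper-extension fuses extra material onto a node, making it longer
        # than its partner; a short node with a weak edge is not trimmed
        if len(node.interval) <= len(partner.interval):
            continue
        sub = sequence[node.interval.start : node.interval.end]
        codes = kmer_codes(sub, k)
        tgt = set(_kmer_position_codes(sequence, partner.interval, k).tolist())
        match_mask = np.array([c >= 0 and c in tgt for c in codes.tolist()])
        # positions already inside the partner match trivially; exclude them
        # so a node fused *into* its partner is trimmed back out of it
        for i in range(match_mask.size):
            if partner.interval.contains(node.interval.start + i):
                match_mask[i] = False
        match_pos = np.flatnonzero(match_mask)
        if match_pos.size == 0:
            continue
        trimmed = _best_match_run(match_pos, node.interval.start)
        if trimmed is None or len(trimmed) >= len(node.interval):
            continue
        if len(trimmed) < 200:  # never trim below the candidate floor
            continue
        node.interval = trimmed
        for (a, b) in list(graph.weights):
            if u in (a, b):
                graph.weights[(a, b)] = edge_weight(
                    sequence, graph.nodes[a].interval, graph.nodes[b].interval, k
                )
    return graph


def _best_match_run(match_pos: np.ndarray, offset: int, join: int = 150) -> Optional[Interval]:
    """Hull of the run of matching positions holding the most matches,
    where runs break at gaps larger than ``join`` bp."""
    if match_pos.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(match_pos) > join) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [match_pos.size]))
    best = max(zip(starts, ends), key=lambda se: se[1] - se[0])
    a, b = best
    return Interval(offset + int(match_pos[a]), offset + int(match_pos[b - 1]) + 1)


def _identity_capped(a: str, b: str, model: IdentityModel) -> float:
    if len(a) == 0 or len(b) == 0:
        return 0.0
    if len(a) * len(b) > _ALIGN_CELL_CAP:
        return kmer_identity_estimate(a, b)
    return global_identity(a, b, model)


@dataclass
class _Context:
    sequence: str
    sequence_id: str
    profile: RepeatProfile
    model: MergeModel
    scorer_config: ScorerConfig
    merger_config: MergerConfig
    config: MatcherConfig
    standard: IdentityModel = STANDARD
    recent: IdentityModel = RECENT


class SpliceMap:
    """Maps positions of a spliced subsequence back to genome coordinates."""

    def __init__(self, span: Interval, removed: Sequence[Interval]) -> None:
        self.span = span
        self.pieces = subtract(span, list(removed))
        self.local_starts: List[int] = []
        off = 0
        for p in self.pieces:
            self.local_starts.append(off)
            off += len(p)
        self.length = off

    def extract(self, sequence: str) -> str:
        return "".join(sequence[p.start : p.end] for p in self.pieces)

    def lift(self, local_pos: int) -> int:
        if local_pos >= self.length:
            return self.pieces[-1].end if self.pieces else self.span.end
        i = int(np.searchsorted(self.local_starts, local_pos, side="right")) - 1
        return self.pieces[i].start + (local_pos - self.local_starts[i])

    def lift_interval_hull(self, iv: Interval) -> Interval:
        start = self.lift(iv.start)
        end = self.lift(iv.end - 1) + 1 if len(iv) else start
        return Interval(start, end)


def _ratio(ctx: _Context, interval: Interval) -> float:
    sc = ctx.profile.score_vector(ctx.sequence_id)
    lo, hi = min(interval.start, sc.size), min(interval.end, sc.size)
    if len(interval) == 0:
        return 0.0
    return int(np.count_nonzero(sc[lo:hi] > 0)) / len(interval)


def _ratio_pieces(ctx: _Context, pieces: Sequence[Interval]) -> float:
    total = sum(len(p) for p in pieces)
    if total == 0:
        return 0.0
    sc = ctx.profile.score_vector(ctx.sequence_id)
    nz = 0
    for p in pieces:
        lo, hi = min(p.start, sc.size), min(p.end, sc.size)
        nz += int(np.count_nonzero(sc[lo:hi] > 0))
    return nz / total


def _units(graph: MatchGraph, nodes: Sequence[int]) -> List[List[int]]:
    """Group overlapping forward/backward nodes into LTR units, sorted."""
    parent = {n: n for n in nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in graph.vertical:
        a, b = tuple(pair)
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    groups: Dict[int, List[int]] = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    units = list(groups.values())
    units.sort(key=lambda u: min(graph.nodes[n].interval.start for n in u))
    return units


def _unit_interval(graph: MatchGraph, unit: Sequence[int]) -> Interval:
    iv = graph.nodes[unit[0]].interval
    for n in unit[1:]:
        iv = iv.hull(graph.nodes[n].interval)
    return iv


def resolve_component(
    graph: MatchGraph,
    component: Sequence[int],
    ctx: _Context,
    component_id: int,
    depth: int = 0,
) -> Tuple[List[ElementCandidate], List[SoloCandidate], List[ComplexRegion]]:
    """Case analysis: single, solo, recently nested, complex, deeply nested."""
    cfg = ctx.config
    pairs = [
        (f, b)
        for f, b in graph.mutual_pairs(component)
        if graph.weight(f, b) >= cfg.min_edge_weight
        and graph.weight(b, f) >= cfg.min_edge_weight
    ]

    def internal_of(f: int, b: int) -> Optional[Interval]:
        s = graph.nodes[f].interval.end
        e = graph.nodes[b].interval.start
        return Interval(s, e) if e > s else None

    qualified = []
    for f, b in pairs:
        internal = internal_of(f, b)
        if internal is not None and _ratio(ctx, internal) >= cfg.min_internal_ratio:
            qualified.append((f, b))

    units = _units(graph, component)
    unit_ivs = [_unit_interval(graph, u) for u in units]
    span = unit_ivs[0]
    for iv in unit_ivs[1:]:
        span = span.hull(iv)

    elements: List[ElementCandidate] = []
    solos: List[SoloCandidate] = []
    complexes: List[ComplexRegion] = []

    def make_element(f: int, b: int, case: str) -> ElementCandidate:
        return ElementCandidate(
            ltr5=graph.nodes[f].interval,
            ltr3=graph.nodes[b].interval,
            case_origin=case,
            weights=(graph.weight(f, b), graph.weight(b, f)),
            component_id=component_id,
        )

    nested = _find_nested_pair(graph, qualified, units, unit_ivs)
    if nested is not None:
        f, b = nested
        inner = make_element(f, b, "single")
        if depth >= cfg.recursion_depth:
            warnings.warn(
                f"recursion depth cap ({cfg.recursion_depth}) reached in "
                f"component {component_id}; emitting inner element only"
            )
            elements.append(inner)
            return elements, solos, complexes
        nested_elements, nested_solos = _resolve_around_inner(
            graph, ctx, inner, span, component_id, depth
        )
        elements.extend(nested_elements)
        solos.extend(nested_solos)
        return elements, solos, complexes

    if len(units) == 3 and len(pairs) >= 2 and len(qualified) != 1:
        # three chained LTRs with ambiguous in-between repetitiveness
        r12 = Interval(unit_ivs[0].end, unit_ivs[1].start)
        r23 = Interval(unit_ivs[1].end, unit_ivs[2].start)
        both_rep = (
            len(r12) > 0
            and len(r23) > 0
            and _ratio(ctx, r12) >= cfg.min_internal_ratio
            and _ratio(ctx, r23) >= cfg.min_internal_ratio
        )
        if both_rep:
            # solo could be any of the three; emit all three pairings
            combos = [(0, 1), (1, 2), (0, 2)]
            for i, j in combos:
                elements.append(
                    ElementCandidate(
                        ltr5=unit_ivs[i],
                        ltr3=unit_ivs[j],
                        case_origin="solo",
                        weights=_unit_pair_weights(graph, units[i], units[j]),
                        component_id=component_id,
                    )
                )
            return elements, solos, complexes

    if qualified:
        for f, b in qualified:
            elements.append(make_element(f, b, "single"))
        # any unit not belonging to an emitted element is a solo LTR
        for u, iv in zip(units, unit_ivs):
            if not any(
                iv.overlaps(e.ltr5) or iv.overlaps(e.ltr3) for e in elements
            ):
                solos.append(SoloCandidate(iv, component_id))
        if solos:
            for e in elements:
                if e.case_origin == "single" and len(units) >= 3:
                    e.case_origin = "solo"
        return elements, solos, complexes

    if len(units) >= 3:
        region = _complex_check(graph, ctx, unit_ivs, span, component_id)
        if region is not None:
            complexes.append(region)
    return elements, solos, complexes


def _unit_pair_weights(graph: MatchGraph, a: Sequence[int], b: Sequence[int]) -> Tuple[float, float]:
    w_fwd = max((graph.weight(x, y) for x in a for y in b), default=0.0)
    w_bwd = max((graph.weight(y, x) for x in a for y in b), default=0.0)
    return (w_fwd, w_bwd)


def _find_nested_pair(
    graph: MatchGraph,
    qualified: List[Tuple[int, int]],
    units: List[List[int]],
    unit_ivs: List[Interval],
) -> Optional[Tuple[int, int]]:
    """The strongest element-shaped qualified pair flanked by units on both
    sides; such a pair signals a (possibly deeply) nested insertion.
    Strength is the pair's weight sum, ties broken by the smaller span."""
    best, best_key = None, None
    for f, b in qualified:
        inner_span = Interval(
            graph.nodes[f].interval.start, graph.nodes[b].interval.end
        )
        internal = Interval(graph.nodes[f].interval.end, graph.nodes[b].interval.start)
        if len(internal) < 200:  # must look like a real element, not a slice pair
            continue
        pair_nodes = {f, b}
        left = any(
            iv.end <= inner_span.start
            for u, iv in zip(units, unit_ivs)
            if not pair_nodes & set(u)
        )
        right = any(
            iv.start >= inner_span.end
            for u, iv in zip(units, unit_ivs)
            if not pair_nodes & set(u)
        )
        if not (left and right):
            continue
        key = (-(graph.weight(f, b) + graph.weight(b, f)), len(inner_span))
        if best_key is None or key < best_key:
            best, best_key = (f, b), key
    return best


def _depth_below(e: ElementCandidate) -> int:
    return 1 + max((_depth_below(c) for c in e.children), default=-1)


def _attach_inner(container: ElementCandidate, inner: ElementCandidate) -> None:
    """Hang the inner element off the deepest containing node of the tree."""
    for child in container.children:
        if child.span.contains_interval(inner.span):
            _attach_inner(child, inner)
            return
    container.children.append(inner)


def _nest_checks(ctx: _Context, container: ElementCandidate, inner: ElementCandidate) -> bool:
    """Repetitiveness of the container's internal part (excluding the nested
    span) plus inner/outer internal identity above the relaxed minimum."""
    cfg = ctx.config

    def spans(e: ElementCandidate) -> List[Interval]:
        out = [e.span]
        for c in e.children:
            out.extend(spans(c))
        return out

    removed = [inner.span] + [s for c in container.children for s in spans(c)]
    pieces = subtract(container.internal, removed)
    pieces = [p for p in pieces if len(p) > 0]
    total = sum(len(p) for p in pieces)
    if total < 50:  # nothing meaningful left to test against
        return True
    if _ratio_pieces(ctx, pieces) < cfg.min_internal_ratio:
        return False
    inner_internal_seq = ctx.sequence[inner.internal.start : inner.internal.end]
    outer_internal_seq = "".join(ctx.sequence[p.start : p.end] for p in pieces)
    if not inner_internal_seq or not outer_internal_seq:
        return True
    ident = _identity_capped(inner_internal_seq, outer_internal_seq, ctx.recent)
    return ident > cfg.nested_min_identity


def _resolve_around_inner(
    graph: MatchGraph,
    ctx: _Context,
    inner: ElementCandidate,
    span: Interval,
    component_id: int,
    depth: int,
) -> Tuple[List[ElementCandidate], List[SoloCandidate]]:
    """Splice the innermost element out of the component span, re-run scorer
    through matcher on the remainder, and stitch the results back together:
    a recursion result containing the inner becomes its parent (after the
    nest confirmation checks); anything else is an independent sibling."""
    inner_span = inner.span
    # widen the working span: outer LTR flanks may extend past the component
    # hull when their score runs fragmented below the candidate floor
    margin = 1000
    work = Interval(max(0, span.start - margin), min(len(ctx.sequence), span.end + margin))
    smap = SpliceMap(work, [inner_span])
    spliced = smap.extract(ctx.sequence)
    if len(spliced) < ctx.scorer_config.k:
        return [inner], []
    sub_elements, sub_solos = _run_subpipeline(ctx, smap, spliced, component_id, depth + 1)
    lifted = [_lift_element(e, smap) for e in sub_elements]
    lifted_solos = [
        SoloCandidate(smap.lift_interval_hull(s.interval), component_id)
        for s in sub_solos
        if not smap.lift_interval_hull(s.interval).overlaps(inner_span)
    ]

    container = None
    siblings: List[ElementCandidate] = []
    for e in lifted:
        e.component_id = component_id
        if e.span.contains_interval(inner_span) or e.internal.overlaps(inner_span):
            if container is None or len(e.span) > len(container.span):
                if container is not None:
                    siblings.append(container)
                container = e
            else:
                siblings.append(e)
        elif e.span.overlaps(span):  # ignore margin-only discoveries
            siblings.append(e)

    out: List[ElementCandidate] = []
    if container is not None and _nest_checks(ctx, container, inner):
        _attach_inner(container, inner)
        container.case_origin = (
            "recently_nested" if _depth_below(container) == 1 else "deeply_nested"
        )
        out.append(container)
    else:
        out.append(inner)
    out.extend(siblings)
    return out, lifted_solos


def _lift_element(e: ElementCandidate, smap: SpliceMap) -> ElementCandidate:
    lifted = ElementCandidate(
        ltr5=smap.lift_interval_hull(e.ltr5),
        ltr3=smap.lift_interval_hull(e.ltr3),
        case_origin=e.case_origin,
        weights=e.weights,
        children=[_lift_element(c, smap) for c in e.children],
        component_id=e.component_id,
    )
    return lifted


def _run_subpipeline(
    ctx: _Context,
    smap: SpliceMap,
    spliced: str,
    component_id: int,
    depth: int,
) -> Tuple[List[ElementCandidate], List[SoloCandidate]]:
    """Scorer -> merger -> detector -> matcher on a spliced subsequence.

    The genome-level repeat profile is reused: its score vector is sliced
    along the splice map rather than retrained.
    """
    sub_id = f"{ctx.sequence_id}::splice{component_id}.{depth}"
    parent_scores = ctx.profile.score_vector(ctx.sequence_id)
    slices = [
        parent_scores[min(p.start, parent_scores.size) : min(p.end, parent_scores.size)]
        for p in smap.pieces
    ]
    sub_scores = np.concatenate(slices) if slices else np.zeros(0)
    if sub_scores.size < len(spliced) - ctx.profile.k + 1:
        sub_scores = np.concatenate(
            [sub_scores, np.zeros(len(spliced) - ctx.profile.k + 1 - sub_scores.size)]
        )
    sub_profile = RepeatProfile(
        k=ctx.profile.k,
        join_distance=ctx.profile.join_distance,
        min_region=ctx.profile.min_region,
    )
    sub_profile.add_sequence(sub_id, sub_scores)

    fwd_track, bwd_track = score(spliced, ctx.scorer_config, sub_id)
    fwd_stretches = stretches_from_track(fwd_track, ctx.merger_config)
    bwd_stretches = stretches_from_track(bwd_track, ctx.merger_config)
    fwd_cands = assemble_candidates(fwd_stretches, ctx.model, sub_profile, sub_id)
    bwd_cands = assemble_candidates(bwd_stretches, ctx.model, sub_profile, sub_id)
    elements, sub_solos, _ = match_candidates(
        spliced,
        sub_id,
        fwd_cands,
        bwd_cands,
        fwd_track,
        bwd_track,
        sub_profile,
        ctx.model,
        ctx.scorer_config,
        ctx.merger_config,
        ctx.config,
        depth=depth,
    )
    return elements, sub_solos


def _complex_check(
    graph: MatchGraph,
    ctx: _Context,
    unit_ivs: List[Interval],
    span: Interval,
    component_id: int,
) -> Optional[ComplexRegion]:
    regions = [
        Interval(a.end, b.start)
        for a, b in zip(unit_ivs, unit_ivs[1:])
        if b.start - a.end >= 100
    ]
    seqs = [ctx.sequence[r.start : r.end] for r in regions]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if _identity_capped(seqs[i], seqs[j], ctx.standard) >= ctx.config.complex_min_identity:
                return ComplexRegion(span, component_id)
    return None


def match_candidates(
    sequence: str,
    sequence_id: str,
    fwd: Sequence[LtrCandidate],
    bwd: Sequence[LtrCandidate],
    fwd_track: ScoreTrack,
    bwd_track: ScoreTrack,
    profile: RepeatProfile,
    model: MergeModel,
    scorer_config: ScorerConfig = ScorerConfig(),
    merger_config: MergerConfig = MergerConfig(),
    config: MatcherConfig = MatcherConfig(),
    depth: int = 0,
) -> Tuple[List[ElementCandidate], List[SoloCandidate], List[ComplexRegion]]:
    """Full matcher stage for one (sub)sequence."""
    graph = build_graph(fwd, bwd, fwd_track, bwd_track, sequence, scorer_config.k)
    trim_hyperextension(graph, sequence, scorer_config.k, config)
    ctx = _Context(
        sequence=sequence,
        sequence_id=sequence_id,
        profile=profile,
        model=model,
        scorer_config=scorer_config,
        merger_config=merger_config,
        config=config,
    )
    elements: List[ElementCandidate] = []
    solos: List[SoloCandidate] = []
    complexes: List[ComplexRegion] = []
    for cid, comp in enumerate(graph.components()):
        e, s, c = resolve_component(graph, comp, ctx, cid, depth)
        elements.extend(e)
        solos.extend(s)
        complexes.extend(c)
    if depth == 0:
        for e in elements:
            _retag_parents(e)
    return elements, solos, complexes


def _retag_parents(e: ElementCandidate) -> None:
    if e.children:
        below = _depth_below(e)
        e.case_origin = "recently_nested" if below == 1 else "deeply_nested"
    for c in e.children:
        _retag_parents(c)


def export_dot(graph: MatchGraph, path: str) -> None:
    """Debug DOT dump of nodes, weighted edges, and vertical connections."""
    with open(path, "w") as fh:
        fh.write("digraph match {\n")
        for n in graph.nodes.values():
            fh.write(
                f'  n{n.node_id} [label="{n.direction[0]}:{n.interval.start}-{n.interval.end}"];\n'
            )
        for (u, v), w in graph.weights.items():
            fh.write(f'  n{u} -> n{v} [label="{w:.2f}"];\n')
        for pair in graph.vertical:
            a, b = tuple(pair)
            fh.write(f"  n{a} -> n{b} [dir=none, style=dashed];\n")
        fh.write("}\n")
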