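import numpy as np
import pytest

from ltrscout import merger, repeat_profile, scorer
from ltrscout.detector import assemble_candidates, constant_model
from ltrscout.intervals import Interval
from ltrscout.matcher import (
    MatcherConfig,
    MatchGraph,
    Node,
    SpliceMap,
    build_graph,
    edge_weight,
    match_candidates,
    trim_hyperextension,
)
from ltrscout.synthetic_data import PlantSpec, generate_genome


def run_front_end(truth_set, model=None):
    """Scorer through detector for the first sequence of a truth set."""
    model = model or constant_model(False)
    sid, seq = truth_set.genome.sequences[0]
    profile = repeat_profile.train(truth_set.genome)
    fwd, bwd = scorer.score(seq, sequence_id=sid)
    fc = assemble_candidates(merger.stretches_from_track(fwd), model, profile, sid)
    bc = assemble_candidates(merger.stretches_from_track(bwd), model, profile, sid)
    return sid, seq, profile, fwd, bwd, fc, bc, model


@pytest.fixture(scope="module")
def single_element():
    specs = [PlantSpec("f", ltr_length=400, internal_length=1500, copy_number=3)]
    return generate_genome(specs, 200_000, seed=21)


class TestBuildGraph:
    def test_single_element_two_nodes_mutual_edges(self, single_element):
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(single_element)
        graph = build_graph(fc, bc, fwd, bwd, seq, 13)
        comps = [c for c in graph.components() if len(c) >= 2]
        assert len(comps) == 3  # one per planted copy
        for comp in comps:
            assert len(comp) == 2
            f, b = sorted(comp, key=lambda n: graph.nodes[n].direction)
            b, f = (f, b) if graph.nodes[f].direction == "backward" else (b, f)
            # zero divergence: every k-mer of one LTR occurs in the other
            assert graph.weight(f, b) == pytest.approx(1.0, abs=0.01)
            assert graph.weight(b, f) == pytest.approx(1.0, abs=0.01)

    def test_three_ltr_chain_vertical_connections(self):
        specs = [
            PlantSpec("f", ltr_length=400, internal_length=1500, copy_number=3),
            PlantSpec("f", kind="solo_ltr", ltr_length=400, gap_before=(2000, 4000)),
        ]
        ts = generate_genome(specs, 220_000, seed=8)
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(ts)
        graph = build_graph(fc, bc, fwd, bwd, seq, 13)
        # the element 3' LTR next to the solo holds a forward and a backward
        # node joined by a vertical connection
        assert len(graph.vertical) >= 1
        for pair in graph.vertical:
            a, b = tuple(pair)
            assert graph.nodes[a].interval.overlaps(graph.nodes[b].interval)
            assert graph.nodes[a].direction != graph.nodes[b].direction

    def test_components_match_union_find_oracle(self, single_element):
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(single_element)
        graph = build_graph(fc, bc, fwd, bwd, seq, 13)
        # independent union-find over declared edges
        ids = sorted(graph.nodes)
        parent = {n: n for n in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in graph.weights:
            parent[find(u)] = find(v)
        for pair in graph.vertical:
            a, b = tuple(pair)
            parent[find(a)] = find(b)
        oracle = {}
        for n in ids:
            oracle.setdefault(find(n), set()).add(n)
        got = {frozenset(c) for c in graph.components()}
        assert got == {frozenset(s) for s in oracle.values()}

    def test_same_direction_edge_rejected(self):
        graph = MatchGraph()
        from ltrscout.detector import LtrCandidate

        for i, d in enumerate(["forward", "forward"]):
            c = LtrCandidate(Interval(i * 1000, i * 1000 + 300), d, 500.0)
            graph.add_node(Node(i, d, c.interval, c))
        with pytest.raises(ValueError):
            graph.add_edge(0, 1, 0.5)

    def test_vertical_requires_overlap(self):
        graph = MatchGraph()
        from ltrscout.detector import LtrCandidate

        for i, d in enumerate(["forward", "backward"]):
            c = LtrCandidate(Interval(i * 1000, i * 1000 + 300), d, 500.0)
            graph.add_node(Node(i, d, c.interval, c))
        with pytest.raises(ValueError):
            graph.add_vertical(0, 1)


class TestEdgeWeight:
    def test_perfect_copy_weight_one(self, rng):
        from helpers import random_dna

        block = random_dna(300, rng)
        seq = block + random_dna(1000, rng) + block
        assert edge_weight(seq, Interval(0, 300), Interval(1300, 1600), 13) == 1.0

    def test_unrelated_weight_zero(self, rng):
        from helpers import random_dna

        seq = random_dna(2000, rng)
        w = edge_weight(seq, Interval(0, 300), Interval(1500, 1800), 13)
        assert w == 0.0


class TestTrimHyperextension:
    def _graph_with_fused_node(self, rng):
        """A 3' LTR wrongly fused with an upstream unrelated repeat."""
        from helpers import random_dna
        from ltrscout.detector import LtrCandidate
        from ltrscout.scorer import ScoreTrack

        ltr = random_dna(400, rng)
        junk = random_dna(500, rng)
        seq = ltr + random_dna(1500, rng) + junk + ltr + random_dna(200, rng)
        graph = MatchGraph()
        five = LtrCandidate(Interval(0, 400), "forward", 2400.0)
        fused = LtrCandidate(Interval(1900, 2800), "backward", 2400.0)
        graph.add_node(Node(0, "forward", five.interval, five))
        graph.add_node(Node(1, "backward", fused.interval, fused))
        w01 = edge_weight(seq, five.interval, fused.interval, 13)
        w10 = edge_weight(seq, fused.interval, five.interval, 13)
        graph.add_edge(0, 1, w01)
        graph.add_edge(1, 0, w10)
        return graph, seq

    def test_fused_node_trimmed_to_matching_region(self, rng):
        graph, seq = self._graph_with_fused_node(rng)
        before = graph.nodes[1].interval
        w_low_before = graph.weight(1, 0)
        trim_hyperextension(graph, seq, 13)
        after = graph.nodes[1].interval
        assert len(after) < len(before)
        # trimmed to roughly the true 400 bp LTR at [2400, 2800)
        assert abs(after.start - 2400) < 30
        assert graph.weight(1, 0) >= w_low_before
        assert graph.weight(1, 0) > 0.9

    def test_symmetric_pair_untouched(self, single_element):
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(single_element)
        graph = build_graph(fc, bc, fwd, bwd, seq, 13)
        before = {n: graph.nodes[n].interval for n in graph.nodes}
        trim_hyperextension(graph, seq, 13)
        assert {n: graph.nodes[n].interval for n in graph.nodes} == before

    def test_trim_monotone_on_random_fixtures(self, rng):
        for _ in range(5):
            graph, seq = self._graph_with_fused_node(rng)
            lows = {
                pair: min(graph.weight(*pair), graph.weight(*pair[::-1]))
                for pair in [(0, 1)]
            }
            sizes = {n: len(graph.nodes[n].interval) for n in graph.nodes}
            trim_hyperextension(graph, seq, 13)
            for n in graph.nodes:
                assert len(graph.nodes[n].interval) <= sizes[n]
            for (u, v), low in lows.items():
                assert min(graph.weight(u, v), graph.weight(v, u)) >= low - 1e-9


class TestResolution:
    def test_single_case(self, single_element):
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(single_element)
        elements, solos, complexes = match_candidates(
            seq, sid, fc, bc, fwd, bwd, profile, model
        )
        assert len(elements) == 3
        truth = [a for a in single_element.annotations]
        for e, t in zip(sorted(elements, key=lambda e: e.span.start), truth):
            assert e.case_origin == "single"
            assert abs(e.span.start - t.element_interval.start) < 30
            assert e.weights[0] >= 0.27 and e.weights[1] >= 0.27

    def test_solo_case_lateralized(self):
        specs = [
            PlantSpec("f", ltr_length=400, internal_length=1500, copy_number=3),
            PlantSpec("f", kind="solo_ltr", ltr_length=400, gap_before=(2000, 4000)),
        ]
        ts = generate_genome(specs, 220_000, seed=8)
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(ts)
        elements, solos, _ = match_candidates(seq, sid, fc, bc, fwd, bwd, profile, model)
        truth_solo = next(a for a in ts.annotations if a.kind == "solo_ltr")
        assert len(solos) == 1
        assert solos[0].interval.overlaps(truth_solo.element_interval)
        assert len(elements) == 3  # the solo never becomes an element LTR

    def test_recently_nested_case(self):
        child = PlantSpec("f", ltr_length=350, internal_length=1200)
        specs = [
            PlantSpec("f", ltr_length=350, internal_length=1200, copy_number=3),
            PlantSpec("f", ltr_length=350, internal_length=1200, nesting=child),
        ]
        ts = generate_genome(specs, 250_000, seed=31)
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(ts)
        elements, _, _ = match_candidates(seq, sid, fc, bc, fwd, bwd, profile, model)
        nested = [e for e in elements if e.children]
        assert len(nested) == 1
        parent = nested[0]
        assert parent.case_origin == "recently_nested"
        kid = parent.children[0]
        assert parent.internal.contains_interval(kid.span)
        truth_parent = next(a for a in ts.annotations if a.name.endswith("_3"))
        assert abs(parent.span.start - truth_parent.element_interval.start) < 40

    def test_deeply_nested_two_levels(self):
        inner = PlantSpec("f", ltr_length=350, internal_length=1400)
        mid = PlantSpec("f", ltr_length=350, internal_length=1400, nesting=inner)
        deep = PlantSpec("f", ltr_length=350, internal_length=1400, nesting=mid)
        specs = [PlantSpec("f", ltr_length=350, internal_length=1400, copy_number=3), deep]
        ts = generate_genome(specs, 250_000, seed=13)
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(ts)
        elements, _, _ = match_candidates(seq, sid, fc, bc, fwd, bwd, profile, model)
        roots = [e for e in elements if e.children]
        assert len(roots) == 1
        outer = roots[0]
        assert outer.case_origin == "deeply_nested"
        middle = outer.children[0]
        assert middle.children, "middle level should hold the innermost element"
        innermost = middle.children[0]
        assert outer.internal.contains_interval(middle.span)
        assert middle.internal.contains_interval(innermost.span)

    def test_config_thresholds_respected(self, single_element):
        sid, seq, profile, fwd, bwd, fc, bc, model = run_front_end(single_element)
        strict = MatcherConfig(min_edge_weight=0.999999, min_internal_ratio=0.33)
        elements, _, _ = match_candidates(
            seq, sid, fc, bc, fwd, bwd, profile, model, config=strict
        )
        for e in elements:
            assert e.weights[0] >= strict.min_edge_weight


class TestSpliceMap:
    def test_roundtrip_extraction(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        smap = SpliceMap(Interval(10, 90), [Interval(30, 50)])
        spliced = smap.extract(seq)
        assert spliced == seq[10:30] + seq[50:90]
        # every spliced position lifts back to the character it came from
        for local in range(len(spliced)):
            assert seq[smap.lift(local)] == spliced[local]

    def test_interval_hull_lifting(self):
        smap = SpliceMap(Interval(0, 100), [Interval(20, 40)])
        # local [10, 30) straddles the splice point: hull spans the removal
        lifted = smap.lift_interval_hull(Interval(10, 30))
        assert lifted == Interval(10, 50)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            MatcherConfig(min_edge_weight=1.5)
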