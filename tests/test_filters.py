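import numpy as np
import pytest

from helpers import random_dna

from ltrscout._kmers import reverse_complement
from ltrscout.filter_postprocess import (
    FilterConfig,
    check_lengths,
    check_similarity,
    drop_orphan_solos,
    filter_element,
    find_ppt,
    find_tsd,
    is_mite,
    longest_common_substring,
)
from ltrscout.intervals import Interval
from ltrscout.matcher import ElementCandidate, SoloCandidate


def element(l5, l3, children=()):
    e = ElementCandidate(ltr5=Interval(*l5), ltr3=Interval(*l3), case_origin="single")
    e.children = list(children)
    return e


class TestLengths:
    def test_typical_element_passes(self):
        assert check_lengths(element((0, 300), (1310, 1620)))

    def test_short_ltr_fails(self):
        assert not check_lengths(element((0, 150), (1000, 1300)))

    def test_ltr_at_upper_bound_fails(self):
        assert not check_lengths(element((0, 7000), (8000, 8300)))

    def test_short_internal_fails(self):
        assert not check_lengths(element((0, 300), (400, 700)))

    def test_nested_span_excluded_from_internal(self):
        # internal is 1200 bp but a nested child covers all but 140 of it
        child_span = ElementCandidate(
            ltr5=Interval(420, 700), ltr3=Interval(1200, 1480), case_origin="single"
        )
        e = element((0, 300), (1500, 1800), children=[child_span])
        assert not check_lengths(e)
        assert check_lengths(element((0, 300), (1500, 1800)))


class TestSimilarity:
    def test_ratio_at_boundary_passes_without_alignment(self, rng):
        seq = random_dna(3000, rng)
        assert check_similarity(element((0, 400), (2000, 2500)), seq)  # 0.8 exactly

    def test_sw_rescue_with_shared_core(self, rng):
        core = random_dna(100, rng)
        ltr_a = random_dna(50, rng) + core + random_dna(50, rng)
        ltr_b = random_dna(150, rng) + core + random_dna(150, rng)
        seq = ltr_a + random_dna(500, rng) + ltr_b
        e = element((0, 200), (700, 1100))  # ratio 0.5 < 0.8
        assert check_similarity(e, seq)

    def test_unrelated_sequences_fail(self, rng):
        seq = random_dna(1400, rng)
        e = element((0, 200), (700, 1100))
        assert not check_similarity(e, seq)


def purine_run(rng, length=15):
    letters = ["A"] * 9 + ["G"] * 4 + ["T"] * (length - 13)
    rng.shuffle(letters)
    return "".join(letters)


def pyrimidine_leaning_dna(n, rng):
    # purine density ~0.3: the poly-A probe cannot drift on background
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, size=n, p=[0.15, 0.35, 0.15, 0.35]).tobytes().decode()


class TestPpt:
    def test_plus_strand_ppt_found(self, rng):
        run = purine_run(rng)
        internal = pyrimidine_leaning_dna(800, rng) + run + pyrimidine_leaning_dna(20, rng)
        seq = random_dna(300, rng) + internal + random_dna(300, rng)
        e = element((0, 300), (300 + len(internal), 300 + len(internal) + 300))
        hit = find_ppt(e, seq)
        assert hit is not None
        interval, reversed_flag = hit
        assert not reversed_flag
        region = seq[interval.start : interval.end]
        assert region.count("A") > region.count("G")

    def test_reverse_orientation_ppt(self, rng):
        # a T-over-C pyrimidine run right after the 5' LTR; the rest of the
        # internal part is C-dominated so the plus-strand probe cannot fire
        run = "TTCTTTTCTTTTCTT"
        # after the run, G-rich filler keeps the T probe localized on the
        # run; the last 400 bp stay C-rich so the plus-strand probe fails
        internal = run + "GGGC" * 100 + "CCCG" * 200
        seq = random_dna(300, rng) + internal + random_dna(300, rng)
        e = element((0, 300), (300 + len(internal), 300 + len(internal) + 300))
        hit = find_ppt(e, seq)
        assert hit is not None
        assert hit[1] is True

    def test_no_purine_signal_fails(self):
        # C-dominated internal: the A probe finds no purine-dense window and
        # the reverse T probe's matched region never has more T than C
        internal = "CCCG" * 300
        seq = "ACGT" * 75 + internal + "ACGT" * 75
        e = element((0, 300), (300 + len(internal), 300 + len(internal) + 300))
        assert find_ppt(e, seq) is None


def mite_ltr(rng, tir_len=20, total=300):
    tir = random_dna(tir_len, rng)
    return tir + random_dna(total - 2 * tir_len, rng) + reverse_complement(tir)


class TestMite:
    def test_both_tir_ltrs_dropped(self, rng):
        a, b = mite_ltr(rng), mite_ltr(rng)
        seq = a + random_dna(900, rng) + b
        e = element((0, 300), (1200, 1500))
        assert is_mite(e, seq)

    def test_one_mite_like_ltr_kept(self, rng):
        a = mite_ltr(rng)
        seq = a + random_dna(900, rng) + random_dna(300, rng)
        e = element((0, 300), (1200, 1500))
        assert not is_mite(e, seq)

    def test_normal_ltrs_kept(self, rng):
        ltr = random_dna(300, rng)
        seq = ltr + random_dna(900, rng) + ltr
        e = element((0, 300), (1200, 1500))
        assert not is_mite(e, seq)


class TestOrphanSolos:
    def test_component_membership(self):
        surviving = [
            ElementCandidate(
                ltr5=Interval(0, 300),
                ltr3=Interval(1000, 1300),
                case_origin="single",
                component_id=1,
            )
        ]
        solos = [SoloCandidate(Interval(2000, 2300), 1), SoloCandidate(Interval(5000, 5300), 2)]
        kept = drop_orphan_solos(solos, surviving)
        assert len(kept) == 1 and kept[0].component_id == 1

    def test_matches_union_find_oracle(self, rng):
        elements = []
        solos = []
        for cid in range(10):
            if rng.random() < 0.5:
                elements.append(
                    ElementCandidate(
                        ltr5=Interval(0, 300),
                        ltr3=Interval(1000, 1300),
                        case_origin="single",
                        component_id=cid,
                    )
                )
            solos.append(SoloCandidate(Interval(cid * 100, cid * 100 + 50), cid))
        alive = {e.component_id for e in elements}
        kept = drop_orphan_solos(solos, elements)
        assert [s.component_id for s in kept] == [
            s.component_id for s in solos if s.component_id in alive
        ]


class TestTsd:
    def test_lcs_oracle(self):
        hits = longest_common_substring("xxABCDEyy", "zzABCDEww")
        assert hits == [(2, 2, 5)]
        assert longest_common_substring("", "abc") == []

    def test_planted_tsd_found_and_boundaries_widened(self, rng):
        tsd = "ACTGA"
        left_flank = random_dna(15, rng) + tsd
        right_flank = tsd + random_dna(15, rng)
        body = random_dna(1500, rng)
        seq = random_dna(100, rng) + left_flank + body + right_flank + random_dna(100, rng)
        start = 100 + len(left_flank)
        end = start + len(body)
        e = element((start, start + 300), (end - 300, end))
        hit = find_tsd(e, seq)
        assert hit is not None
        left, right = hit
        assert seq[left.start : left.end] == seq[right.start : right.end]
        assert len(left) >= 5
        assert e.span.start == left.end and e.span.end == right.start

    def test_short_common_substring_rejected(self):
        seq = "A" * 100 + "CGT" * 500 + "T" * 100
        # flanks share at most a 3-mer by construction
        e = element((100, 400), (1300, 1600))
        config = FilterConfig()
        up = seq[80:100]
        down = seq[1600:1620]
        hits = longest_common_substring(up, down)
        best = hits[0][2] if hits else 0
        got = find_tsd(e, seq, config)
        if best < 4:
            assert got is None

    def test_identical_flanks_maximal_tsd(self, rng):
        flank = random_dna(20, rng)
        seq = random_dna(80, rng) + flank + random_dna(1500, rng) + flank + random_dna(80, rng)
        e = element((100, 400), (1300, 1600))
        hit = find_tsd(e, seq)
        assert hit is not None
        assert len(hit[0]) == 20


class TestFilterElement:
    def test_conjunction_semantics(self, rng):
        # an element failing PPT is rejected regardless of other filters
        ltr = random_dna(300, rng)
        internal = "CCCG" * 300
        seq = ltr + internal + ltr
        e = element((0, 300), (300 + len(internal), 600 + len(internal)))
        ok, ppt = filter_element(e, seq)
        assert not ok and ppt is None

    def test_valid_element_passes_with_ppt(self, rng):
        ltr = random_dna(300, rng)
        internal = random_dna(900, rng) + purine_run(rng) + random_dna(20, rng)
        seq = ltr + internal + ltr
        e = element((0, 300), (300 + len(internal), 600 + len(internal)))
        ok, ppt = filter_element(e, seq)
        assert ok and ppt is not None


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_ltr=0)
    with pytest.raises(ValueError):
        FilterConfig(min_len_ratio=1.5)
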