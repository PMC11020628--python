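import numpy as np
import pytest

from ltrscout.detector import (
    MergeModel,
    N_FEATURES,
    assemble_candidates,
    constant_model,
    featurize,
    train_model,
)
from ltrscout.intervals import Interval
from ltrscout.merger import Stretch
from ltrscout.repeat_profile import RepeatProfile


def profile_from_scores(sc, sid="s"):
    p = RepeatProfile(k=13)
    p.add_sequence(sid, np.asarray(sc, dtype=float))
    return p


def stretch(start, size, height, direction="forward"):
    return Stretch(
        interval=Interval(start, start + size),
        direction=direction,
        height=float(height),
        label="keep" if size >= 16 else "delete",
    )


class TestFeaturize:
    def test_symmetric_identical_pair(self):
        r = 2.5
        profile = profile_from_scores(np.full(200, r))
        s1, s2 = stretch(0, 50, 1000), stretch(50, 50, 1000)
        f = featurize(s1, s2, profile, "s")
        assert f.shape == (N_FEATURES,)
        assert f[0] == 50 and f[1] == 50
        assert f[2] == 0 and f[3] == 0 and f[4] == 0 and f[5] == 0
        assert f[6] == r and f[7] == r
        assert f[8] == 0  # zero-length gap
        assert f[9] == 1.0

    def test_distinct_repeat_regions_flag_zero(self):
        sc = np.zeros(1000)
        sc[0:200] = 1.0
        sc[800:1000] = 1.0
        profile = profile_from_scores(sc)
        f = featurize(stretch(0, 150, 500), stretch(820, 150, 500), profile, "s")
        assert f[9] == 0.0

    def test_matches_recount_oracle(self, rng):
        for _ in range(25):
            sc = rng.random(500) * (rng.random(500) < 0.6)
            profile = profile_from_scores(sc)
            a = int(rng.integers(0, 150))
            sa = int(rng.integers(16, 80))
            gap = int(rng.integers(0, 60))
            sb = int(rng.integers(16, 80))
            s1 = stretch(a, sa, int(rng.integers(400, 5000)))
            s2 = stretch(a + sa + gap, sb, int(rng.integers(400, 5000)))
            f = featurize(s1, s2, profile, "s")
            w1, w2 = sc[a : a + sa], sc[a + sa + gap : a + sa + gap + sb]
            wg = sc[a + sa : a + sa + gap]

            def nzmed(v):
                nz = v[v > 0]
                return float(np.median(nz)) if nz.size else 0.0

            assert f[0] == sa and f[1] == sb and f[2] == gap
            assert f[3] == abs(s1.height - s2.height)
            assert f[4] == pytest.approx(abs(nzmed(w1) - nzmed(w2)))
            assert f[5] == pytest.approx(abs(w1.mean() - w2.mean()))
            assert f[6] == pytest.approx(w1.mean())
            assert f[7] == pytest.approx(w2.mean())
            assert f[8] == pytest.approx(wg.mean() if gap else 0.0)

    def test_overlapping_pair_rejected(self):
        profile = profile_from_scores(np.zeros(100))
        with pytest.raises(ValueError):
            featurize(stretch(0, 50, 100), stretch(20, 50, 100), profile, "s")

    def test_mixed_direction_rejected(self):
        profile = profile_from_scores(np.zeros(200))
        with pytest.raises(ValueError):
            featurize(
                stretch(0, 50, 100),
                stretch(60, 50, 100, direction="backward"),
                profile,
                "s",
            )


def separable_data(rng, n=400):
    """Labels determined by a margin on a linear score: separable."""
    X = np.abs(rng.normal(size=(n, N_FEATURES)))
    X[:, 9] = (rng.random(n) < 0.5).astype(float)
    y = (X[:, 2] + X[:, 3] < 1.4).astype(int)
    return X, y


class TestTrainModel:
    def test_separable_data_high_f1(self):
        rng = np.random.default_rng(0)
        X, y = separable_data(rng)
        model, metrics = train_model(X, y, seed=0, n_search_iterations=10)
        assert metrics["test_f1"] >= 0.95
        assert model.weights.shape == (N_FEATURES,)

    def test_label_permutation_near_prevalence_baseline(self):
        rng = np.random.default_rng(1)
        X, y = separable_data(rng)
        y_perm = rng.permutation(y)
        _, metrics = train_model(X, y_perm, seed=1, n_search_iterations=10)
        prevalence = y_perm.mean()
        # F1 of an uninformed classifier ~ 2p/(1+p); allow a wide band
        baseline = 2 * prevalence / (1 + prevalence)
        assert metrics["test_f1"] <= baseline + 0.2

    def test_single_class_rejected(self):
        X = np.zeros((10, N_FEATURES))
        with pytest.raises(ValueError):
            train_model(X, np.zeros(10, dtype=int), seed=0)


class TestModelSerialization:
    def test_roundtrip(self, tmp_path):
        model = MergeModel(
            weights=np.arange(10, dtype=float),
            bias=-0.5,
            feature_means=np.ones(9),
            feature_sds=np.full(9, 2.0),
            metadata={"note": "test"},
        )
        path = tmp_path / "model.json"
        model.save(str(path))
        back = MergeModel.load(str(path))
        assert np.array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        x = np.arange(10, dtype=float).reshape(1, -1)
        assert back.decision(x) == pytest.approx(model.decision(x))

    def test_bad_file_rejected(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            MergeModel.load(str(path))

    def test_f10_never_standardized(self):
        model = MergeModel(
            weights=np.zeros(10),
            bias=0.0,
            feature_means=np.full(9, 5.0),
            feature_sds=np.full(9, 3.0),
        )
        x = np.ones((1, 10))
        z = model.standardize(x)
        assert z[0, 9] == 1.0  # untouched
        assert z[0, 0] == pytest.approx((1 - 5) / 3)


class TestAssembleCandidates:
    def test_lone_stretch_becomes_candidate(self):
        profile = profile_from_scores(np.zeros(1000))
        cands = assemble_candidates(
            [stretch(0, 300, 1000)], constant_model(False), profile, "s"
        )
        assert len(cands) == 1
        assert cands[0].interval == Interval(0, 300)

    def test_short_isolated_stretch_discarded(self):
        profile = profile_from_scores(np.zeros(1000))
        cands = assemble_candidates(
            [stretch(0, 150, 1000)], constant_model(False), profile, "s"
        )
        assert cands == []

    def test_accept_all_model_fuses_chain(self):
        profile = profile_from_scores(np.zeros(2000))
        stretches = [stretch(i * 120, 100, 1000) for i in range(5)]
        cands = assemble_candidates(stretches, constant_model(True), profile, "s")
        assert len(cands) == 1
        assert cands[0].interval == Interval(0, 4 * 120 + 100)

    def test_gap_cap_blocks_distant_merges(self):
        profile = profile_from_scores(np.zeros(10_000))
        stretches = [stretch(0, 300, 1000), stretch(5000, 300, 1000)]
        cands = assemble_candidates(stretches, constant_model(True), profile, "s")
        assert len(cands) == 2

    def test_candidates_sorted_disjoint_and_long_enough(self, rng):
        profile = profile_from_scores(rng.random(5000))
        stretches = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1, 200))
            size = int(rng.integers(5, 120))
            stretches.append(stretch(pos, size, int(rng.integers(400, 3000))))
            pos += size
        cands = assemble_candidates(stretches, constant_model(True), profile, "s")
        for c in cands:
            assert c.size >= 200
        for a, b in zip(cands, cands[1:]):
            assert a.interval.end <= b.interval.start
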