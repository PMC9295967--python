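"""Speaker-disjoint splits, mismatch null, objective, regularization search."""

import numpy as np
import pytest

from avmtf import crossval as cv
from avmtf.crossval import (NullDistribution, make_split, matched_correlation,
                            mismatch_null, objective, optimize_regularization)
from avmtf.synthetic import flagship_ground_truth, generate_feature_corpus


@pytest.fixture(scope="module")
def small_corpus():
    gt = flagship_ground_truth(seed=11)
    return generate_feature_corpus(gt, 10, 2, 500, seed=11)


class TestMakeSplit:
    def test_partition_arithmetic(self):
        vids = [f"v{i}" for i in range(100)]
        spks = [f"s{i // 5}" for i in range(100)]  # 20 speakers x 5 videos
        split = make_split(vids, spks, test_frac=0.1, n_folds=5, seed=0)
        split.validate()
        assert len(split.test_videos) == 10  # 2 speakers' worth
        assert sorted(split.train_videos + split.test_videos) == sorted(vids)
        for fold in split.folds:
            assert 15 <= len(fold) <= 20  # 3-4 speakers per fold

    def test_determinism(self):
        vids = [f"v{i}" for i in range(60)]
        spks = [f"s{i % 12}" for i in range(60)]
        s1 = make_split(vids, spks, seed=5)
        s2 = make_split(vids, spks, seed=5)
        assert s1.test_videos == s2.test_videos and s1.folds == s2.folds

    @pytest.mark.parametrize("seed", range(5))
    def test_speaker_disjointness_random_corpora(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 80))
        vids = [f"v{i}" for i in range(n)]
        spks = [f"s{rng.integers(8)}" for _ in range(n)]
        while len(set(spks)) < 7:
            spks = [f"s{rng.integers(8)}" for _ in range(n)]
        make_split(vids, spks, n_folds=5, seed=seed).validate()

    def test_too_few_speakers_rejected(self):
        with pytest.raises(ValueError, match="speakers"):
            make_split(["a", "b", "c"], ["s1", "s2", "s3"], n_folds=5)


class TestMismatchNull:
    def test_no_matched_pairing_possible(self, rng):
        # with per-video constant-offset signatures, a matched pairing
        # would give correlation exactly 1; assert none occurs
        a = {f"v{i}": np.tile(rng.standard_normal(50)[:, None], (1, 2)) + i
             for i in range(5)}
        null = mismatch_null(a, {k: v.copy() for k, v in a.items()}, n=300, seed=0)
        assert null.samples.shape == (300, 2)
        # identical matched series would correlate at 1.0 exactly
        assert not np.any(null.samples > 1 - 1e-12)

    def test_white_noise_null_width(self, rng):
        T = 750
        a = {f"v{i}": rng.standard_normal((T, 3)) for i in range(6)}
        v = {f"v{i}": rng.standard_normal((T, 3)) for i in range(6)}
        null = mismatch_null(a, v, n=1000, seed=1)
        sd = null.samples.std()
        assert 0.7 / np.sqrt(T) < sd < 1.4 / np.sqrt(T)
        assert np.abs(null.samples.mean()) < 3 / np.sqrt(T * 1000) * 10

    def test_requested_sample_count(self, rng):
        a = {f"v{i}": rng.standard_normal((40, 2)) for i in range(3)}
        null = mismatch_null(a, a, n=123, seed=2)
        assert null.n == 123

    def test_single_speaker_warns(self, rng):
        a = {f"v{i}": rng.standard_normal((40, 2)) for i in range(3)}
        speaker_of = {k: "s0" for k in a}
        with pytest.warns(UserWarning, match="one speaker"):
            mismatch_null(a, a, n=10, seed=0, speaker_of=speaker_of)

    def test_truncation_to_shorter(self, rng):
        a = {"v0": rng.standard_normal((50, 2)), "v1": rng.standard_normal((80, 2))}
        null = mismatch_null(a, a, n=20, seed=3)
        assert np.all(np.isfinite(null.samples))


class TestObjective:
    def test_shift_invariance(self):
        null = NullDistribution(np.random.default_rng(0).normal(0, 0.1, (500, 4)))
        matched = np.array([0.5, 0.4, 0.01, -0.2])
        base = objective(matched, null)
        shifted = objective(matched + 0.3,
                            NullDistribution(null.samples + 0.3))
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_no_significant_components_gives_zero(self):
        null = NullDistribution(np.random.default_rng(1).normal(0, 0.1, (500, 3)))
        assert objective(np.array([-0.5, -0.5, -0.5]), null) == 0.0

    def test_noise_corpus_objective_near_zero(self):
        gt = flagship_ground_truth(seed=21)
        c = generate_feature_corpus(gt, 8, 2, 400, seed=21, independent=True)
        split = make_split(c.video_ids, c.speaker_ids, n_folds=5, seed=0)
        obj = cv.cv_objective(c, split, 1e-2, 1e-2, null_size=200, seed=0)
        # each fold contributes only chance-level exceedances
        assert abs(obj) < 2.0

    def test_signal_corpus_objective_positive(self, small_corpus):
        split = make_split(small_corpus.video_ids, small_corpus.speaker_ids,
                           n_folds=5, seed=0)
        obj = cv.cv_objective(small_corpus, split, 1e-2, 1e-2, null_size=200, seed=0)
        assert obj > 2.0  # two strong planted components over five folds


class TestOptimizer:
    @staticmethod
    def known_function(lam_a, lam_v):
        # smooth 2-D bump on the log-lambda square, maximum at (1e-2, 1e-3)
        la, lv = np.log10(lam_a), np.log10(lam_v)
        return -((la + 2) ** 2 + (lv + 3) ** 2)

    def test_gp_finds_known_maximum(self):
        res = optimize_regularization(self.known_function, n_initial=5,
                                      n_calls=12, seed=3)
        best = np.log10(res.best_lambda)
        assert abs(best[0] + 2) < 0.75 and abs(best[1] + 3) < 0.75
        assert res.best_objective == max(res.objectives)

    def test_log_uniform_initialization(self):
        seen = []
        def record(a, b):
            seen.append((np.log10(a), np.log10(b)))
            return 0.0
        for s in range(40):
            optimize_regularization(record, n_initial=5, n_calls=5, seed=s)
        arr = np.asarray(seen).ravel()
        assert arr.min() > -5 and arr.max() < 0
        # roughly uniform over [-5, 0]: each unit bin holds a fair share
        hist, _ = np.histogram(arr, bins=5, range=(-5, 0))
        assert hist.min() > 0.5 * arr.size / 5 * 0.5

    def test_random_fallback(self):
        res = optimize_regularization(self.known_function, n_initial=5,
                                      n_calls=8, seed=0, use_gp=False)
        assert all(a == "random" for a in res.acquisitions)
        assert len(res.objectives) == 8

    def test_budget_below_initial_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            optimize_regularization(self.known_function, n_initial=5, n_calls=3)


class TestFinalize:
    def test_two_planted_components_significant(self, small_corpus):
        split = make_split(small_corpus.video_ids, small_corpus.speaker_ids,
                           n_folds=5, seed=1)
        res = cv.finalize_and_test(small_corpus, split, 1e-2, 1e-2,
                                   null_size=500, seed=1)
        assert res.reported.sum() >= 2
        top2 = np.sort(res.test_correlations)[::-1][:2]
        assert np.all(top2 > 0.5)

    def test_min_correlation_rule_suppresses(self, small_corpus):
        split = make_split(small_corpus.video_ids, small_corpus.speaker_ids,
                           n_folds=5, seed=1)
        res = cv.finalize_and_test(small_corpus, split, 1e-2, 1e-2,
                                   null_size=200, seed=1, min_correlation=0.99)
        # raising the floor above every correlation suppresses reporting
        assert res.reported.sum() == 0
        assert res.significant.sum() >= 2

    def test_empty_test_set_rejected(self, small_corpus):
        split = make_split(small_corpus.video_ids, small_corpus.speaker_ids,
                           n_folds=5, seed=1)
        split.test_videos = []
        with pytest.raises(ValueError, match="test"):
            cv.finalize_and_test(small_corpus, split, 1e-2, 1e-2)

    def test_matched_per_video_option(self, small_corpus, rng):
        vids = small_corpus.video_ids[:4]
        a = {v: rng.standard_normal((100, 3)) for v in vids}
        b = {v: x + 0.5 * rng.standard_normal((100, 3)) for v, x in a.items()}
        concat = matched_correlation(a, b, vids)
        per_vid = matched_correlation(a, b, vids, per_video=True)
        assert np.all(concat > 0.5) and np.all(per_vid > 0.5)
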