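"""Dataset construction, SVM training, calibration and evaluation."""

import numpy as np
import pytest

from premir.classifier import (
    MirnaSVM,
    MirnaSVMResults,
    build_datasets,
    default_sizes,
    eval_confusion,
)

FIVE = tuple("abcde")
SMALL_C = (0.25, 4.0, 64.0)
SMALL_G = (0.01, 0.1, 1.0)


def blobs(rng, n_pos=60, n_neg=300, sep=2.0):
    Xp = rng.normal(sep / 2, 0.4, (n_pos, 5))
    Xn = rng.normal(-sep / 2, 0.4, (n_neg, 5))
    return Xp, Xn


class TestBuildDatasets:
    def test_reference_pool_sizes(self):
        assert default_sizes(224, 5677) == (184, 184, 40, 1000)

    def test_proportional_scaling_for_small_pools(self):
        assert default_sizes(20, 100) == (16, 16, 4, 18)

    def test_split_reproducible_and_disjoint(self, rng):
        Xp = np.arange(40.0).reshape(20, 2)
        Xn = np.arange(200.0).reshape(100, 2) + 1000
        a = build_datasets(Xp, Xn, seed=3)
        b = build_datasets(Xp, Xn, seed=3)
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.X_test1, b.X_test1)
        rows = {tuple(r) for r in a.X_train} | {tuple(r) for r in a.X_test1} | {
            tuple(r) for r in a.X_test2
        }
        assert len(rows) == sum(a.sizes)  # no example in two sets

    def test_insufficient_pool_is_a_sizing_error(self):
        with pytest.raises(ValueError, match="need"):
            build_datasets(np.zeros((10, 3)), np.zeros((50, 3)), sizes=(8, 8, 4, 100))


class TestTraining:
    def test_separable_blobs_reach_full_cv_accuracy(self, rng):
        Xp, Xn = blobs(rng)
        split = build_datasets(Xp, Xn, sizes=(40, 40, 20, 100), seed=0)
        res = MirnaSVM(split.X_train, split.y_train, FIVE).fit(SMALL_C, SMALL_G, seed=0)
        assert res.cv_accuracy == 100.0
        ev = res.evaluate(split)
        assert ev.se == 100.0 and ev.sp == 100.0 and ev.acc == 100.0

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        Xp, Xn = blobs(rng, 100, 100)
        X = np.vstack([Xp, Xn])
        y = rng.permutation(np.r_[np.ones(100), -np.ones(100)]).astype(int)
        res = MirnaSVM(X, y, FIVE).fit(SMALL_C, SMALL_G, seed=0)
        assert 35.0 <= res.cv_accuracy <= 70.0  # ~50% plus selection noise

    def test_same_seed_same_model(self, rng):
        Xp, Xn = blobs(rng)
        split = build_datasets(Xp, Xn, sizes=(40, 40, 20, 100), seed=1)
        m = MirnaSVM(split.X_train, split.y_train, FIVE)
        r1, r2 = m.fit(SMALL_C, SMALL_G, seed=5), m.fit(SMALL_C, SMALL_G, seed=5)
        assert (r1.C, r1.gamma) == (r2.C, r2.gamma)
        assert np.array_equal(r1.predict_prob(split.X_test2), r2.predict_prob(split.X_test2))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            MirnaSVM(np.zeros((10, 5)), np.ones(10), FIVE)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    Xp, Xn = blobs(rng)
    split = build_datasets(Xp, Xn, sizes=(40, 40, 20, 100), seed=0)
    res = MirnaSVM(split.X_train, split.y_train, FIVE).fit(SMALL_C, SMALL_G, seed=0)
    return split, res


class TestPrediction:
    def test_probabilities_bounded_and_ordered(self, fitted):
        split, res = fitted
        p_pos = res.predict_prob(split.X_test1)
        p_neg = res.predict_prob(split.X_test2)
        assert ((0 <= p_pos) & (p_pos <= 1)).all()
        assert p_pos.mean() > p_neg.mean()

    def test_label_matches_half_probability_threshold(self, fitted):
        split, res = fitted
        X = np.vstack([split.X_test1, split.X_test2])
        assert np.array_equal(res.predict(X), np.where(res.predict_prob(X) > 0.5, 1, -1))

    def test_fingerprint_mismatch_rejected(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError, match="mismatch"):
            res.predict_prob(np.zeros((3, 7)))

    def test_serialization_round_trip_bit_identical(self, fitted, tmp_path):
        split, res = fitted
        path = tmp_path / "model.json"
        res.save(path)
        back = MirnaSVMResults.load(path)
        assert np.array_equal(
            res.predict_prob(split.X_test2), back.predict_prob(split.X_test2)
        )
        assert back.summary() == res.summary()


class TestEvaluation:
    def test_perfect_and_trivial_classifiers(self):
        perfect = eval_confusion(tp=40, fn=0, tn=1000, fp=0)
        assert (perfect.se, perfect.sp, perfect.acc) == (100.0, 100.0, 100.0)
        always_pos = eval_confusion(tp=40, fn=0, tn=0, fp=1000)
        assert (always_pos.se, always_pos.sp, always_pos.acc) == (100.0, 0.0, 50.0)

    def test_accuracy_is_the_unweighted_mean(self):
        # SE 100 and SP 91.2 on 40/1000 test sets: ACC must come out 95.6,
        # not the pooled 91.5
        ev = eval_confusion(tp=40, fn=0, tn=912, fp=88)
        assert ev.se == pytest.approx(100.0)
        assert ev.sp == pytest.approx(91.2)
        assert ev.acc == pytest.approx(95.6)

    def test_empty_test_set_is_an_error(self):
        with pytest.raises(ValueError):
            eval_confusion(0, 0, 10, 0)

    def test_roc_is_monotone(self, rng):
        Xp, Xn = blobs(rng, sep=1.0)
        split = build_datasets(Xp, Xn, sizes=(40, 40, 20, 100), seed=0)
        res = MirnaSVM(split.X_train, split.y_train, FIVE).fit(SMALL_C, SMALL_G, seed=0)
        ev = res.evaluate(split)
        fpr = [p[0] for p in ev.roc_points]
        tpr = [p[1] for p in ev.roc_points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        # at least as good as the majority-class accuracy of the pooled tests
        assert ev.auc >= 100 / 120
        assert ev.auc <= 1.0
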