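import math

import numpy as np
import pytest

from qsppred.features import EncodingSpec
from qsppred.model import (
    ConfusionCounts,
    CVConfig,
    MetricsReport,
    QspClassifier,
    TrainedModel,
    auc,
    confusion_at_threshold,
    cross_validate,
    metrics,
    predict,
    roc_points,
    train_final,
)
from qsppred.seqio import NEGATIVE, POSITIVE, Peptide, PeptideSet, scramble


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting (independent oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect(self):
        r = metrics(ConfusionCounts(10, 10, 0, 0))
        assert r.accuracy == 100.0 and r.mcc == pytest.approx(1.0)
        assert r.sensitivity == 100.0 and r.specificity == 100.0

    def test_inverted(self):
        r = metrics(ConfusionCounts(0, 0, 10, 10))
        assert r.accuracy == 0.0 and r.mcc == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        r = metrics(ConfusionCounts(tp=9, tn=8, fp=2, fn=1))
        assert r.accuracy == pytest.approx(85.0)
        assert r.mcc == pytest.approx((9 * 8 - 2 * 1) / math.sqrt(11 * 10 * 10 * 9))
        assert r.sensitivity == pytest.approx(90.0)
        assert r.specificity == pytest.approx(80.0)

    def test_agrees_with_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 50, 4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            r = metrics(ConfusionCounts(tp, tn, fp, fn))
            total = tp + tn + fp + fn
            assert r.sensitivity == pytest.approx(100 * tp / (tp + fn))
            assert r.specificity == pytest.approx(100 * tn / (tn + fp))
            assert r.accuracy == pytest.approx(100 * (tp + tn) / total)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom > 0:
                assert r.mcc == pytest.approx((tp * tn - fp * fn) / math.sqrt(denom))
                assert -1.0 - 1e-12 <= r.mcc <= 1.0 + 1e-12
            else:
                assert r.mcc == 0.0 and r.mcc_undefined

    def test_zero_marginal_flagged_not_fatal(self):
        r = metrics(ConfusionCounts(tp=5, tn=0, fp=3, fn=0))
        assert r.mcc == 0.0 and r.mcc_undefined

    def test_class_swap_symmetry(self):
        a = metrics(ConfusionCounts(tp=9, tn=8, fp=2, fn=1))
        b = metrics(ConfusionCounts(tp=8, tn=9, fp=1, fn=2))
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.mcc == pytest.approx(b.mcc)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 2, 1, -1, -2], [1, 1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 8, [1, 1, 1, 1, 0, 0, 0, 0]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
            scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(1 - auc(-scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_trapezoidal_roc_integration_agrees(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        pts = roc_points(scores, labels).sort_values("fpr")
        trap = np.trapezoid(pts["tpr"], pts["fpr"])
        assert trap == pytest.approx(auc(scores, labels))


class TestCrossValidation:
    def test_separable_fixture_high_accuracy(self, separable, quick_cv):
        rep, (C, g) = cross_validate(separable, EncodingSpec("AAC"), quick_cv)
        assert rep.accuracy >= 95.0
        assert rep.auc >= 0.99
        assert len(rep.fold_accuracies) == 10

    def test_permuted_labels_chance_level(self, separable, quick_cv):
        rng = np.random.default_rng(13)
        labels = [p.label for p in separable]
        perm = rng.permutation(labels)
        shuffled = PeptideSet(
            [Peptide(p.id, p.seq, lab) for p, lab in zip(separable, perm)]
        )
        rep, _ = cross_validate(
            shuffled, EncodingSpec("AAC"),
            CVConfig(n_folds=10, seed=13, c_grid=(1.0,), g_grid=(0.1,)),
        )
        se = 100 * math.sqrt(0.25 / len(shuffled))
        assert abs(rep.accuracy - 50.0) <= 3 * se + 1e-9

    def test_scrambled_negatives_aac_chance_level(self, small_sets, quick_cv):
        # AAC of a peptide equals AAC of its scramble, so the classes are
        # indistinguishable under AAC and grouped CV (peptide with its
        # scramble twin in the same fold) scores at chance
        pos, _ = small_sets
        neg = scramble(pos, seed=21)
        data = PeptideSet(
            [p.with_label(POSITIVE) for p in pos] + list(neg), name="scr"
        )
        groups = [p.id for p in pos] * 2
        rep, _ = cross_validate(data, EncodingSpec("AAC"), quick_cv, groups=groups)
        se = 100 * math.sqrt(0.25 / len(data))
        assert abs(rep.accuracy - 50.0) <= 3 * se

    def test_scramble_twin_leakage_anti_learns(self, small_sets, quick_cv):
        # without grouping, each held-out peptide's composition-identical
        # twin sits in training with the opposite label, and the kernel
        # model anti-predicts it: accuracy falls far *below* chance. This
        # is why the scrambled-negative evaluation must group twin pairs.
        pos, _ = small_sets
        neg = scramble(pos, seed=21)
        data = PeptideSet(
            [p.with_label(POSITIVE) for p in pos] + list(neg), name="scr"
        )
        rep, _ = cross_validate(data, EncodingSpec("AAC"), quick_cv)
        assert rep.accuracy < 40.0

    def test_deterministic_given_seed(self, separable, quick_cv):
        a = cross_validate(separable, EncodingSpec("AAC"), quick_cv)
        b = cross_validate(separable, EncodingSpec("AAC"), quick_cv)
        assert a[1] == b[1]
        assert a[0].as_dict() == b[0].as_dict()
        assert a[0].fold_accuracies == b[0].fold_accuracies

    def test_class_smaller_than_folds_rejected(self):
        tiny = PeptideSet(
            [Peptide(f"p{i}", "ACDEF", POSITIVE) for i in range(3)]
            + [Peptide(f"n{i}", "GGGGG", NEGATIVE) for i in range(12)]
        )
        with pytest.raises(ValueError):
            cross_validate(tiny, EncodingSpec("AAC"), CVConfig(n_folds=10))


@pytest.fixture(scope="module")
def fitted(separable, quick_cv):
    return QspClassifier(separable, EncodingSpec("AAC"), quick_cv).fit()


class TestTrainedModel:
    def test_training_positives_mostly_positive(self, fitted, separable):
        out = fitted.predict(separable)
        pos_ids = [p.id for p in separable if p.label == POSITIVE]
        frac = (out.loc[pos_ids, "label"] == "positive").mean()
        assert frac > 0.95

    def test_threshold_monotonicity(self, fitted, separable):
        d = fitted.trained.decision_values(separable)
        y = np.array([1 if p.label == POSITIVE else 0 for p in separable])
        prev_sn, prev_sp = 101.0, -1.0
        for t in np.linspace(d.min() - 1, d.max() + 1, 9):
            r = metrics(confusion_at_threshold(d, y, t))
            assert r.sensitivity <= prev_sn + 1e-9
            assert r.specificity >= prev_sp - 1e-9
            prev_sn, prev_sp = r.sensitivity, r.specificity

    def test_extreme_thresholds(self, fitted, separable):
        m = fitted.trained
        d = m.decision_values(separable)
        assert ((d >= np.inf).sum(), (d >= -np.inf).sum()) == (0, len(separable))

    def test_save_load_round_trip_bit_identical(self, fitted, separable, tmp_path):
        path = tmp_path / "model.joblib"
        fitted.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            loaded.decision_values(separable), fitted.trained.decision_values(separable)
        )
        assert loaded.spec == fitted.trained.spec

    def test_validate_uses_same_path_as_predict(self, fitted, separable):
        rep = fitted.validate(separable)
        out = fitted.predict(separable)
        predicted_pos = (out["label"] == "positive").sum()
        assert predicted_pos == rep.confusion.tp + rep.confusion.fp

    def test_unscorable_peptides_reported_not_dropped(self, separable, quick_cv):
        fitted = QspClassifier(separable, EncodingSpec("N5C5Bin"), quick_cv).fit()
        out = fitted.predict(PeptideSet([Peptide("tiny", "ACD"), Peptide("ok", "ACDEFGHIK")]))
        assert len(out) == 2
        assert not out.loc["tiny", "scorable"] and out.loc["tiny", "label"] == "unscorable"
        assert out.loc["ok", "scorable"]

    def test_empty_set_empty_report(self, fitted):
        assert len(fitted.predict(PeptideSet([]))) == 0

    def test_summary_mentions_key_numbers(self, fitted):
        text = fitted.summary()
        assert "CV accuracy" in text and "MCC" in text and "gamma" in text


class TestModelSelection:
    def test_tie_break_prefers_smaller_C(self, separable):
        # on a perfectly separable set many grid points reach 100%; the
        # smallest C among the best must be selected
        cfg = CVConfig(n_folds=5, seed=0, c_grid=(1.0, 4.0, 16.0), g_grid=(0.1,))
        rep, (C, g) = cross_validate(separable, EncodingSpec("AAC"), cfg)
        if rep.accuracy == 100.0:
            rep1, _ = cross_validate(
                separable, EncodingSpec("AAC"),
                CVConfig(n_folds=5, seed=0, c_grid=(1.0,), g_grid=(0.1,)),
            )
            if rep1.accuracy == 100.0:
                assert C == 1.0
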