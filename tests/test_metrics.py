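"""Alignment/uniformity closed forms and the classification metric suite."""

import warnings

import numpy as np
import pytest

from drmargin import (
    accuracy,
    alignment,
    auc,
    classification_report,
    confusion_tally,
    precision_recall_f1,
    uniformity,
)


def auc_pair_oracle(scores, truth):
    """Probability a random positive outscores a random negative (ties 1/2)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestAlignment:
    def test_identical_pairs_zero(self):
        x = np.eye(3)
        assert alignment(x, x) == 0.0

    def test_orthogonal_and_antipodal(self):
        assert alignment([[1.0, 0.0]], [[0.0, 1.0]]) == pytest.approx(2.0)
        assert alignment([[1.0, 0.0]], [[-1.0, 0.0]]) == pytest.approx(4.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            alignment(np.empty((0, 2)), np.empty((0, 2)))

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(20, 4)), rng.normal(size=(20, 4))
        loop = np.mean([np.sum((a - b) ** 2) for a, b in zip(x, y)])
        assert alignment(x, y) == pytest.approx(loop, abs=1e-6)


class TestUniformity:
    def test_collapsed_set_zero(self):
        assert uniformity(np.tile([1.0, 0.0], (5, 1))) == pytest.approx(0.0)

    def test_antipodal_pair_closed_form(self):
        val = uniformity(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert val == pytest.approx(np.log((2 + 2 * np.exp(-8)) / 4), abs=1e-9)

    def test_spread_beats_collapsed(self):
        spread = np.vstack([np.eye(3), -np.eye(3)])
        collapsed = np.tile([1.0, 0.0, 0.0], (6, 1))
        assert uniformity(spread) < uniformity(collapsed)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 5))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        m = len(pts)
        loop = np.log(
            np.mean([np.exp(-2 * np.sum((pts[i] - pts[j]) ** 2)) for i in range(m) for j in range(m)])
        )
        assert uniformity(pts) == pytest.approx(loop, abs=1e-6)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert uniformity(pts @ q) == pytest.approx(uniformity(pts), abs=1e-9)


class TestConfusionTally:
    def test_perfect_predictions(self):
        t = confusion_tally([0, 1, 2], [0, 1, 2], 3)
        assert t.fp.sum() == 0 and t.fn.sum() == 0

    def test_binary_counting_example(self):
        t = confusion_tally([1, 1, 1, 0, 1, 0], [1, 1, 1, 1, 0, 0], 2)
        assert (t.tp[1], t.fp[1], t.fn[1]) == (3, 1, 1)

    def test_counts_conserve_totals(self):
        rng = np.random.default_rng(3)
        pred, truth = rng.integers(0, 4, 50), rng.integers(0, 4, 50)
        t = confusion_tally(pred, truth, 4)
        assert np.all(t.tp + t.fp + t.fn + t.tn == 50)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_tally([0, 1], [0], 2)


class TestPrecisionRecallF1:
    def test_hand_counted_values(self):
        # TP=8, FP=2, FN=4 on the positive class
        pred = [1] * 10 + [0] * 4
        truth = [1] * 8 + [0] * 2 + [1] * 4
        t = confusion_tally(pred, truth, 2)
        prec, rec, f1 = precision_recall_f1(t, "binary")
        assert prec == pytest.approx(80.0)
        assert rec == pytest.approx(100 * 8 / 12, abs=0.01)
        assert f1 == pytest.approx(72.73, abs=0.01)

    def test_macro_is_mean_of_per_class(self):
        rng = np.random.default_rng(4)
        pred, truth = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
        t = confusion_tally(pred, truth, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec_m, rec_m, f1_m = precision_recall_f1(t, "macro")
            per = [
                precision_recall_f1(
                    confusion_tally((pred == c).astype(int), (truth == c).astype(int), 2),
                    "binary",
                )
                for c in range(3)
            ]
        assert prec_m == pytest.approx(np.mean([p[0] for p in per]))
        assert rec_m == pytest.approx(np.mean([p[1] for p in per]))
        assert f1_m == pytest.approx(np.mean([p[2] for p in per]))

    def test_zero_denominator_warns_and_reports_zero(self):
        t = confusion_tally([0, 0], [1, 1], 2)  # class 1 never predicted
        with pytest.warns(UserWarning, match="zero denominator"):
            prec, _, _ = precision_recall_f1(t, "binary")
        assert prec == 0.0


class TestAccuracy:
    def test_values(self):
        assert accuracy([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]) == 100.0
        assert accuracy([0, 1], [1, 0]) == 0.0
        assert accuracy([0, 1, 2, 3, 4], [0, 1, 2, 3, 0]) == pytest.approx(80.0)

    def test_binary_accuracy_equals_tally_formula(self):
        rng = np.random.default_rng(5)
        pred, truth = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        t = confusion_tally(pred, truth, 2)
        assert accuracy(pred, truth) == pytest.approx(100 * (t.tp[1] + t.tn[1]) / 40)


class TestAuc:
    def test_perfect_and_derived_values(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 100.0
        assert auc(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 0, 1, 0])) == pytest.approx(75.0)

    def test_all_tied_scores_give_half(self):
        assert auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == pytest.approx(50.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(6)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=40)  # ties on purpose
        truth = rng.integers(0, 2, 40)
        assert auc(scores, truth) == pytest.approx(auc_pair_oracle(scores, truth), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        truth = rng.integers(0, 2, 30)
        base = auc(scores, truth)
        assert auc(np.exp(scores), truth) == pytest.approx(base, abs=1e-9)
        assert auc(3.0 * scores + 5.0, truth) == pytest.approx(base, abs=1e-9)

    def test_macro_skips_absent_class_with_warning(self):
        scores = np.random.default_rng(8).random((10, 3))
        truth = np.array([0, 1] * 5)  # class 2 absent
        with pytest.warns(UserWarning, match="class 2 absent"):
            val = auc(scores, truth, "macro_ovr")
        assert 0.0 <= val <= 100.0


class TestClassificationReport:
    def test_perfect_binary_classifier(self):
        truth = np.array([0, 1, 0, 1])
        rep = classification_report(np.array([0.1, 0.9, 0.2, 0.8]), truth, truth, "binary")
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.auc) == (100, 100, 100, 100, 100)

    def test_majority_predictor_on_balanced_binary(self):
        truth = np.array([0, 1] * 10)
        pred = np.ones(20, int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = classification_report(np.full(20, 0.5), pred, truth, "binary")
        assert rep.accuracy == pytest.approx(50.0)
        assert rep.auc == pytest.approx(50.0)

    def test_fields_match_component_operations(self):
        rng = np.random.default_rng(9)
        scores = rng.random((30, 4))
        scores /= scores.sum(axis=1, keepdims=True)
        pred = scores.argmax(axis=1)
        truth = rng.integers(0, 4, 30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = classification_report(scores, pred, truth, "multiclass")
            t = confusion_tally(pred, truth, 4)
            prec, rec, f1 = precision_recall_f1(t, "macro")
            assert rep.precision == pytest.approx(prec)
            assert rep.recall == pytest.approx(rec)
            assert rep.f1 == pytest.approx(f1)
            assert rep.accuracy == pytest.approx(accuracy(pred, truth))
            assert rep.auc == pytest.approx(auc(scores, truth, "macro_ovr"))

    def test_json_round_trip(self, tmp_path):
        import json

        truth = np.array([0, 1, 1, 0])
        rep = classification_report(np.array([0.2, 0.7, 0.6, 0.4]), truth, truth, "binary")
        doc = json.loads(rep.to_json(tmp_path / "rep.json"))
        assert doc["mode"] == "binary"
        assert set(doc["per_class"]) == {"0", "1"}
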