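"""Metric formulas vs. brute-force counting oracles and scikit-learn."""

import warnings

import numpy as np
import pytest
from sklearn import metrics as skm

from hahnet import metrics as hm


# ---------------------------------------------------------------------------
# confusion matrix

def test_confusion_identity_pattern():
    cm = hm.confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3], 4)
    np.testing.assert_array_equal(cm, np.eye(4, dtype=int))


def test_confusion_empty_inputs():
    np.testing.assert_array_equal(hm.confusion_matrix([], [], 3), np.zeros((3, 3)))


def test_confusion_label_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        hm.confusion_matrix([0, 4], [0, 0], 4)


def test_confusion_matches_double_loop_oracle():
    rng = np.random.default_rng(50)
    y_true = rng.integers(0, 4, 50)
    y_pred = rng.integers(0, 4, 50)
    cm = hm.confusion_matrix(y_true, y_pred, 4)
    oracle = np.zeros((4, 4), dtype=int)
    for t, p in zip(y_true, y_pred):
        oracle[t, p] += 1
    np.testing.assert_array_equal(cm, oracle)
    np.testing.assert_array_equal(cm.sum(axis=1),
                                  [np.sum(y_true == c) for c in range(4)])


# ---------------------------------------------------------------------------
# binary metrics (the five formulas)

def test_perfect_classifier_closed_form():
    m = hm.binary_metrics(hm.ConfusionCounts(tp=2, tn=2, fp=0, fn=0))
    assert m == hm.BinaryMetrics(1.0, 1.0, 1.0, 1.0, 1.0)


def test_uninformative_counts_closed_form():
    m = hm.binary_metrics(hm.ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
    assert m.mcc == 0.0
    assert m.accuracy == 0.5


def test_hand_computed_example():
    # tp=3, fp=1, fn=2, tn=4: direct evaluation of the five formulas
    m = hm.binary_metrics(hm.ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
    assert m.accuracy == pytest.approx(7 / 10)
    assert m.recall == pytest.approx(3 / 5)
    assert m.precision == pytest.approx(3 / 4)
    assert m.f_score == pytest.approx(6 / 9)
    assert m.mcc == pytest.approx((3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6))


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError, match="zero"):
        hm.binary_metrics(hm.ConfusionCounts(0, 0, 0, 0))


def test_zero_denominator_returns_zero_with_warning():
    with pytest.warns(UserWarning, match="precision"):
        m = hm.binary_metrics(hm.ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
    assert m.precision == 0.0


def test_binary_formulas_match_arithmetic_oracle_on_random_tables():
    """200 seeded random count tables vs. literal formula evaluation."""
    rng = np.random.default_rng(123)
    checked = 0
    for _ in range(200):
        tp, tn, fp, fn = (int(v) for v in rng.integers(1, 30, 4))
        m = hm.binary_metrics(hm.ConfusionCounts(tp, tn, fp, fn))
        total = tp + tn + fp + fn
        assert m.accuracy == pytest.approx((tp + tn) / total, abs=1e-12)
        assert m.recall == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.precision == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert m.f_score == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
        den = np.sqrt(float(tp + fp) * (tp + fn) * (fp + tn) * (fn + tn))
        assert m.mcc == pytest.approx((tp * tn - fp * fn) / den, abs=1e-12)
        checked += 1
    assert checked == 200


# ---------------------------------------------------------------------------
# multiclass MCC

def test_multiclass_mcc_reduces_to_binary_at_k2():
    rng = np.random.default_rng(7)
    for _ in range(200):
        tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
        cm = np.array([[tp, fn], [fp, tn]])  # class 0 = positive
        binary = hm.binary_metrics(hm.ConfusionCounts(tp, tn, fp, fn)).mcc
        assert hm.multiclass_mcc(cm) == pytest.approx(binary, abs=1e-12)


def test_multiclass_mcc_matches_sklearn():
    rng = np.random.default_rng(8)
    y_true = rng.integers(0, 4, 300)
    y_pred = rng.integers(0, 4, 300)
    cm = hm.confusion_matrix(y_true, y_pred, 4)
    assert hm.multiclass_mcc(cm) == pytest.approx(
        skm.matthews_corrcoef(y_true, y_pred), abs=1e-12)


# ---------------------------------------------------------------------------
# ROC / AUC

def auc_pair_oracle(y_true, s, c):
    """Brute-force concordant-pair count with half credit for ties."""
    pos = s[y_true == c]
    neg = s[y_true != c]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation():
    y = np.array([0, 0, 1, 1])
    scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    aucs, macro = hm.roc_auc_ovr(y, scores, 2)
    np.testing.assert_allclose(aucs, [1.0, 1.0])
    assert macro == 1.0


def test_auc_constant_scores_give_half():
    y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
    scores = np.full((8, 4), 0.25)
    aucs, macro = hm.roc_auc_ovr(y, scores, 4)
    np.testing.assert_allclose(aucs, 0.5)
    assert macro == pytest.approx(0.5)


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(30)
    y = rng.integers(0, 4, 30)
    scores = rng.random((30, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    aucs, _ = hm.roc_auc_ovr(y, scores, 4)
    for c in range(4):
        assert aucs[c] == pytest.approx(auc_pair_oracle(y, scores[:, c], c),
                                        abs=1e-12)


def test_auc_matches_sklearn_and_monotone_invariant():
    rng = np.random.default_rng(31)
    y = rng.integers(0, 4, 120)
    scores = rng.random((120, 4))
    aucs, macro = hm.roc_auc_ovr(y, scores, 4)
    for c in range(4):
        assert aucs[c] == pytest.approx(
            skm.roc_auc_score((y == c).astype(int), scores[:, c]), abs=1e-12)
    # strictly monotone transform of scores leaves AUC unchanged
    aucs2, _ = hm.roc_auc_ovr(y, np.exp(3 * scores), 4)
    np.testing.assert_allclose(aucs, aucs2, atol=1e-12)


def test_auc_absent_class_excluded_with_warning():
    y = np.array([0, 0, 1, 1])
    scores = np.random.default_rng(1).random((4, 3))
    with pytest.warns(UserWarning, match="class 2 absent"):
        aucs, macro = hm.roc_auc_ovr(y, scores, 3)
    assert np.isnan(aucs[2])
    assert macro == pytest.approx(np.nanmean(aucs[:2]))


def test_roc_curve_matches_sklearn():
    rng = np.random.default_rng(32)
    y = rng.integers(0, 3, 40)
    s = rng.random(40)
    fpr, tpr, _ = hm.roc_curve_points(y, s, 1, 3)
    sk_fpr, sk_tpr, _ = skm.roc_curve((y == 1).astype(int), s,
                                      drop_intermediate=False)
    np.testing.assert_allclose(fpr, sk_fpr, atol=1e-12)
    np.testing.assert_allclose(tpr, sk_tpr, atol=1e-12)
    # trapezoidal area under our points equals the rank-based AUC
    aucs, _ = hm.roc_auc_ovr(y, np.c_[s, s, s], 3)
    assert np.trapezoid(tpr, fpr) == pytest.approx(aucs[1], abs=1e-12)


# ---------------------------------------------------------------------------
# multiclass report

def perfect_case(n=20, k=4, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, k, n)
    scores = np.full((n, k), 0.02)
    scores[np.arange(n), y] = 1 - 0.02 * (k - 1)
    return y, y.copy(), scores


def test_report_perfect_classifier_all_ones():
    y_true, y_pred, scores = perfect_case()
    r = hm.multiclass_report(y_true, y_pred, scores, 4)
    for val in (r.accuracy, r.precision, r.recall, r.f_score, r.mcc, r.auc):
        assert val == pytest.approx(1.0)


def test_report_macro_equals_mean_of_per_class_binaries():
    rng = np.random.default_rng(20)
    y_true = rng.integers(0, 4, 20)
    y_pred = rng.integers(0, 4, 20)
    scores = rng.random((20, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small n: some empty denominators
        r = hm.multiclass_report(y_true, y_pred, scores, 4)
        per = [hm.binary_metrics(c)
               for c in hm.one_vs_rest_counts(y_true, y_pred, 4)]
    assert r.precision == pytest.approx(np.mean([m.precision for m in per]))
    assert r.recall == pytest.approx(np.mean([m.recall for m in per]))
    assert r.f_score == pytest.approx(np.mean([m.f_score for m in per]))
    assert r.accuracy == pytest.approx(np.mean(y_true == y_pred))


def test_report_random_predictions_near_chance():
    """Balanced 4-class labels with uniformly random predictions: accuracy
    within 3 sigma of 1/4 (binomial), MCC within 3 sigma of 0 (~1/sqrt(n))."""
    n = 4000
    rng = np.random.default_rng(1000)
    y_true = np.repeat(np.arange(4), n // 4)
    y_pred = rng.integers(0, 4, n)
    scores = rng.random((n, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    r = hm.multiclass_report(y_true, y_pred, scores, 4)
    sigma_acc = np.sqrt(0.25 * 0.75 / n)
    assert abs(r.accuracy - 0.25) < 3 * sigma_acc
    assert abs(r.mcc) < 3 / np.sqrt(n - 1)


def test_report_matches_sklearn_aggregates():
    rng = np.random.default_rng(21)
    y_true = rng.integers(0, 4, 200)
    y_pred = rng.integers(0, 4, 200)
    scores = rng.random((200, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    r = hm.multiclass_report(y_true, y_pred, scores, 4)
    assert r.precision == pytest.approx(
        skm.precision_score(y_true, y_pred, average="macro"), abs=1e-12)
    assert r.recall == pytest.approx(
        skm.recall_score(y_true, y_pred, average="macro"), abs=1e-12)
    assert r.f_score == pytest.approx(
        skm.f1_score(y_true, y_pred, average="macro"), abs=1e-12)
    assert r.auc == pytest.approx(
        skm.roc_auc_score(y_true, scores, multi_class="ovr",
                          average="macro"), abs=1e-12)


def test_label_permutation_equivariance():
    rng = np.random.default_rng(22)
    y_true = rng.integers(0, 4, 100)
    y_pred = rng.integers(0, 4, 100)
    scores = rng.random((100, 4))
    scores /= scores.sum(axis=1, keepdims=True)
    perm = np.array([2, 0, 3, 1])   # class c -> perm[c]
    r1 = hm.multiclass_report(y_true, y_pred, scores, 4)
    inv = np.argsort(perm)
    r2 = hm.multiclass_report(perm[y_true], perm[y_pred], scores[:, inv], 4)
    assert r2.accuracy == pytest.approx(r1.accuracy)
    assert r2.precision == pytest.approx(r1.precision)
    assert r2.mcc == pytest.approx(r1.mcc)
    assert r2.auc == pytest.approx(r1.auc)
    for c in range(4):
        assert r2.per_class[perm[c]]["f_score"] == pytest.approx(
            r1.per_class[c]["f_score"])


def test_report_input_validation():
    y = np.array([0, 1])
    ok = np.array([[0.5, 0.5], [0.5, 0.5]])
    with pytest.raises(ValueError, match="equal length"):
        hm.multiclass_report(y, [0], ok, 2)
    with pytest.raises(ValueError, match="sum to 1"):
        hm.multiclass_report(y, y, ok * 2, 2)
    with pytest.raises(ValueError, match="columns"):
        hm.multiclass_report(y, y, ok, 3)


def test_report_serialization_roundtrip(tmp_path):
    y_true, y_pred, scores = perfect_case(n=16)
    r = hm.multiclass_report(y_true, y_pred, scores, 4)
    jpath = tmp_path / "report.json"
    hm.write_report_json(r, jpath)
    import json
    loaded = json.loads(jpath.read_text())
    assert loaded["accuracy"] == 1.0
    assert np.array(loaded["confusion"]).shape == (4, 4)

    hm.write_confusion_csv(r.confusion, tmp_path / "cm.csv",
                           labels=["0", "1+", "2+", "3+"])
    lines = (tmp_path / "cm.csv").read_text().strip().splitlines()
    assert len(lines) == 5 and lines[0].endswith("0,1+,2+,3+")

    paths = hm.write_roc_csv(y_true, scores, 4, tmp_path / "roc")
    assert len(paths) == 4
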