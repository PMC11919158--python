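import math

import numpy as np
import pytest
from scipy import stats

from varcalib import (
    ComputationError,
    LabeledScores,
    LogisticModel,
    auc,
    confusion_at,
    fit_logistic,
    ks_two_sample,
    metric_curves,
    predict_log_odds,
    roc_curve,
    youden_optimal,
)


def pair_count_auc(pos, neg):
    """Independent oracle: concordant-pair fraction with half-credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# --- logistic model ---------------------------------------------------------

def test_fit_logistic_symmetric_data_gives_zero_coefficients():
    scores = [0.1, 0.5, 0.9, 0.1, 0.5, 0.9]
    labels = [True, True, True, False, False, False]
    m = fit_logistic(LabeledScores(scores, labels))
    assert abs(m.intercept) < 1e-8
    assert abs(m.slope) < 1e-8


def test_fit_logistic_flags_complete_separation():
    m = fit_logistic(LabeledScores([0.9, 0.8, 0.2, 0.1], [True, True, False, False]))
    assert m.separated
    assert m.slope > 0
    assert np.isfinite(m.intercept) and np.isfinite(m.slope)
    # The capped fit still classifies the boundary correctly.
    assert m.predict_log_odds(0.9) > 0 > m.predict_log_odds(0.1)


def test_fit_logistic_single_class_raises():
    with pytest.raises(ComputationError):
        fit_logistic(LabeledScores([0.1, 0.2], [True, True]))


def test_fit_logistic_identical_scores_raises():
    with pytest.raises(ComputationError):
        fit_logistic(LabeledScores([0.5, 0.5], [True, False]))


def test_fit_logistic_matches_reference_glm():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 500)
    y = rng.random(500) < 1 / (1 + np.exp(-(-2.0 + 4.0 * x)))
    m = fit_logistic(LabeledScores(x, y))
    import statsmodels.api as sm

    ref = sm.GLM(y.astype(float), sm.add_constant(x), family=sm.families.Binomial()).fit()
    assert m.intercept == pytest.approx(ref.params[0], abs=1e-6)
    assert m.slope == pytest.approx(ref.params[1], abs=1e-6)


@pytest.mark.parametrize(
    "intercept,slope,score,expected",
    [
        (-7.474, 11.192, 0.0, -7.474),
        (-7.474, 11.192, 1.0, 3.718),
        (-4.714, 0.09892, 0.0, -4.714),
    ],
)
def test_predict_log_odds(intercept, slope, score, expected):
    m = LogisticModel(intercept=intercept, slope=slope)
    assert predict_log_odds(m, score) == pytest.approx(expected, abs=1e-9)
    p = m.predict_probability(score)
    assert p == pytest.approx(1 / (1 + math.exp(-expected)), abs=1e-12)


# --- ROC / AUC / Youden ------------------------------------------------------

def _labeled(pos, neg):
    return LabeledScores(list(pos) + list(neg), [True] * len(pos) + [False] * len(neg))


def test_roc_curve_perfect_separation_contains_ideal_point():
    curve = roc_curve(_labeled([0.9, 0.8], [0.2, 0.1]))
    points = set(zip(curve.fpr.tolist(), curve.tpr.tolist()))
    assert (0.0, 1.0) in points
    assert auc(curve) == 1.0


def test_roc_curve_degenerate_scores_is_diagonal():
    curve = roc_curve(_labeled([0.5], [0.5]))
    assert curve.tpr.tolist() == [0.0, 1.0]
    assert curve.fpr.tolist() == [0.0, 1.0]
    assert auc(curve) == 0.5


def test_roc_curve_hand_enumerated_points():
    curve = roc_curve(_labeled([0.8, 0.4], [0.6, 0.2]))
    points = list(zip(curve.fpr.tolist(), curve.tpr.tolist()))
    assert (0.0, 0.5) in points
    assert (0.5, 1.0) in points
    assert points[0] == (0.0, 0.0)
    assert points[-1] == (1.0, 1.0)
    assert auc(curve) == pytest.approx(0.75)


def test_roc_curve_monotone_and_bounded():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = rng.integers(2, 40)
        labels = np.r_[True, False, rng.random(n) < 0.5]
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=labels.size)
        curve = roc_curve(LabeledScores(scores, labels))
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert 0 <= curve.tpr.min() and curve.tpr.max() == 1.0
        assert curve.thresholds[0] == np.inf and curve.thresholds[-1] == -np.inf


def test_roc_single_class_raises():
    with pytest.raises(ComputationError):
        roc_curve(LabeledScores([0.1, 0.2], [False, False]))


def test_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n_pos, n_neg = rng.integers(1, 20, size=2)
        pos = rng.choice(np.linspace(0, 1, 11), size=n_pos)
        neg = rng.choice(np.linspace(0, 1, 11), size=n_neg)
        got = auc(roc_curve(_labeled(pos, neg)))
        assert got == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(23)
    scores = rng.random(60)
    labels = rng.random(60) < 0.4
    labels[:2] = [True, False]
    base = auc(roc_curve(LabeledScores(scores, labels)))
    for f in (lambda s: 2 * s + 1, np.exp, lambda s: s**3):
        assert auc(roc_curve(LabeledScores(f(scores), labels))) == pytest.approx(base)


def test_youden_perfect_and_degenerate():
    assert youden_optimal(roc_curve(_labeled([0.9], [0.1])))[3] == 1.0
    assert youden_optimal(roc_curve(_labeled([0.5], [0.5])))[3] == 0.0


def test_youden_tie_breaks_toward_larger_threshold():
    thr, tpr, fpr, j = youden_optimal(roc_curve(_labeled([0.8, 0.4], [0.6, 0.2])))
    assert j == pytest.approx(0.5)
    assert thr == pytest.approx(0.7)
    assert (tpr, fpr) == (0.5, 0.0)


# --- KS ----------------------------------------------------------------------

def test_ks_identical_samples():
    r = ks_two_sample([0.1, 0.3], [0.1, 0.3])
    assert r.d_stat == 0.0
    assert r.p_value == 1.0


def test_ks_disjoint_supports():
    r = ks_two_sample([0.1, 0.3], [0.7, 0.9])
    assert r.d_stat == 1.0
    assert r.at_score == 0.3


def test_ks_hand_computed_interleaved():
    r = ks_two_sample([0.1, 0.3], [0.2, 0.8])
    assert r.d_stat == pytest.approx(0.5)
    assert r.at_score == pytest.approx(0.3)


def test_ks_signed_not_absolute():
    # Positives scoring *lower* than negatives: the signed difference
    # ECDF_neg - ECDF_pos is never positive, so D stays 0.
    r = ks_two_sample([0.7, 0.9], [0.1, 0.3])
    assert r.d_stat == 0.0


def test_ks_empty_input_raises():
    with pytest.raises(ComputationError):
        ks_two_sample([], [0.1])


def test_ks_statistic_and_p_match_scipy():
    rng = np.random.default_rng(29)
    for _ in range(20):
        neg = rng.normal(0, 1, int(rng.integers(30, 80)))
        pos = rng.normal(0.8, 1, int(rng.integers(30, 80)))
        r = ks_two_sample(neg, pos)
        # The signed statistic matches scipy's one-sided ("greater") statistic.
        ref = stats.ks_2samp(neg, pos, alternative="greater", method="asymp")
        assert r.d_stat == pytest.approx(ref.statistic, abs=1e-12)
        # The p-value is the classical asymptotic Kolmogorov series at
        # sqrt(mn/(m+n)) * D; scipy's kstwobign is the oracle for the series.
        en = np.sqrt(len(neg) * len(pos) / (len(neg) + len(pos)))
        assert r.p_value == pytest.approx(
            stats.kstwobign.sf(en * r.d_stat), rel=1e-9, abs=1e-15
        )


# --- confusion metrics --------------------------------------------------------

def test_confusion_perfect_split():
    c = confusion_at(_labeled([0.9], [0.1]), 0.5)
    assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)
    assert c.accuracy == c.sensitivity == c.specificity == c.ppv == c.npv == 1.0


def test_confusion_threshold_above_positive():
    c = confusion_at(_labeled([0.9], [0.1]), 0.95)
    assert c.sensitivity == 0.0
    assert c.npv == 0.5
    assert c.ppv is None  # no predicted positives: undefined, not zero


def test_confusion_threshold_above_everything_flags_ppv():
    c = confusion_at(_labeled([0.2, 0.3], [0.1]), 10.0)
    assert c.ppv is None
    assert c.npv == pytest.approx(1 / 3)


def test_metric_curves_shape_and_monotonicity():
    rng = np.random.default_rng(31)
    scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=50)
    labels = rng.random(50) < 0.5
    labels[:2] = [True, False]
    data = LabeledScores(scores, labels)
    table = metric_curves(data)
    assert len(table) == np.unique(scores).size
    assert (table["threshold"].diff().dropna() < 0).all()
    # Thresholds descend row-wise, so sensitivity is non-decreasing down the
    # table (equivalently: non-increasing in the threshold).
    assert (table["sensitivity"].diff().dropna() >= 0).all()


def test_youden_equals_ks_on_same_data():
    rng = np.random.default_rng(37)
    for _ in range(25):
        n = rng.integers(4, 60)
        labels = np.r_[True, False, rng.random(n) < 0.5]
        scores = rng.choice(np.round(np.linspace(0, 1, 9), 3), size=labels.size)
        data = LabeledScores(scores, labels)
        j = youden_optimal(roc_curve(data))[3]
        d = ks_two_sample(scores[~labels], scores[labels]).d_stat
        assert j == d  # exact: both derive from the same integer counts
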