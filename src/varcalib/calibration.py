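"""Threshold calibration of pathogenicity scores against a binary truth set.

Pathogenic/likely-pathogenic (P/LP) variants are the positive reference
and benign/likely-benign (B/LB) variants the negative reference.  The
module provides a maximum-likelihood binary logistic model of the log
odds of pathogenicity given a score, the empirical ROC curve and its
area, the Youden index J = max(TPR - FPR), the two-sample
Kolmogorov-Smirnov statistic between class-conditional score
distributions, and threshold-wise confusion metrics.

Conventions shared by every routine here:

* the classification rule is "predict pathogenic iff score >= threshold";
* empirical CDFs use the <= convention (fraction of variants with score
  less than or equal to the evaluation point);
* the KS statistic is the signed maximum of ECDF_negative minus
  ECDF_positive, which under these conventions equals the maximum of
  TPR - FPR over thresholds, exactly.

All curve statistics are computed from integer class counts so the
KS/Youden identity holds bit-for-bit, not merely to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .variants import ClinvarBin, Consequence, VariantRecord

#: Predetermined supporting-pathogenic thresholds for the two tools.
DEFAULT_THRESHOLDS = {"revel": 0.644, "cadd": 20.0}

#: Cap on the magnitude of the linear predictor under complete separation.
_SEPARATION_LOGIT_CAP = 30.0


@dataclass(frozen=True)
class LabeledScores:
    """Scores with binary labels (True = positive/pathogenic reference)."""

    scores: np.ndarray
    labels: np.ndarray

    def __init__(self, scores: Iterable[float], labels: Iterable[bool]) -> None:
        s = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
        y = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels, dtype=bool)
        if s.shape != y.shape or s.ndim != 1:
            raise ValidationError("scores and labels must be 1-D and of equal length")
        if s.size == 0:
            raise ValidationError("scores must be non-empty")
        if not np.all(np.isfinite(s)):
            raise ValidationError("scores must be finite")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @classmethod
    def from_records(
        cls, records: Iterable[VariantRecord], tool: str
    ) -> "LabeledScores":
        """Build a truth set from missense records classified B/LB or P/LP.

        Records missing the tool's score are excluded.
        """
        scores, labels = [], []
        for r in records:
            if r.consequence_class is not Consequence.MISSENSE:
                continue
            if r.clinvar_bin not in (ClinvarBin.B_LB, ClinvarBin.P_LP):
                continue
            s = r.score(tool)
            if s is None:
                continue
            scores.append(s)
            labels.append(r.clinvar_bin is ClinvarBin.P_LP)
        if not scores:
            raise ComputationError(f"no scored B/LB or P/LP missense records for {tool}")
        return cls(scores, labels)

    def _require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ComputationError("need at least one positive and one negative")


@dataclass
class LogisticModel:
    """Binary logistic model: log-odds(P/LP) = intercept + slope * score."""

    intercept: float
    slope: float
    converged: bool = True
    separated: bool = False
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def predict_log_odds(self, score) -> float:
        return self.intercept + self.slope * np.asarray(score, dtype=float)

    def predict_probability(self, score) -> float:
        return 1.0 / (1.0 + np.exp(-self.predict_log_odds(score)))


def predict_log_odds(model: LogisticModel, score) -> float:
    """Log-odds of pathogenic classification at ``score`` under ``model``."""
    return model.predict_log_odds(score)


def fit_logistic(
    data: LabeledScores,
    weights: Optional[Sequence[float]] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence is declared when the change in log-likelihood drops below
    ``tol`` (default 1e-10) or after ``max_iter`` iterations.  Complete
    separation (all positive scores strictly above all negative scores or
    vice versa — a monotone likelihood with no finite maximiser) is
    detected up front and reported as a flagged fit whose linear
    predictor is capped at +/-30 across the observed score range, rather
    than returning divergent coefficients.

    ``weights`` are optional per-observation frequency weights (defaults
    to 1, i.e. unique-variant fitting).
    """
    data._require_both_classes()
    x = data.scores
    y = data.labels.astype(float)
    if np.ptp(x) == 0:
        raise ComputationError("cannot fit a slope: all scores are identical")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative, same length as scores")

    pos_min, pos_max = x[data.labels].min(), x[data.labels].max()
    neg_min, neg_max = x[~data.labels].min(), x[~data.labels].max()
    if pos_min > neg_max or pos_max < neg_min:
        # Complete separation: return the capped boundary fit.
        sign = 1.0 if pos_min > neg_max else -1.0
        cut = (pos_min + neg_max) / 2.0 if sign > 0 else (pos_max + neg_min) / 2.0
        half_range = max(np.ptp(x) / 2.0, np.finfo(float).tiny)
        slope = sign * _SEPARATION_LOGIT_CAP / half_range
        return LogisticModel(
            intercept=-slope * cut,
            slope=slope,
            converged=False,
            separated=True,
            n_iter=0,
            log_likelihood=0.0,
        )

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))
        wls = w * p * (1 - p)
        grad = X.T @ (w * (y - p))
        info = (X * wls[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
            raise ComputationError("singular information matrix in IRLS") from exc
        beta = beta + step
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return LogisticModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        converged=converged,
        separated=False,
        n_iter=n_iter,
        log_likelihood=ll,
    )


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve swept over descending score cut-points.

    ``thresholds[i]`` represents the half-open score interval realising the
    operating point ``(fpr[i], tpr[i])`` by its midpoint (+inf for the
    (0, 0) corner, -inf for the (1, 1) corner).  The integer class counts
    behind each point are retained so downstream statistics (Youden J) can
    be computed in exact integer arithmetic.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tp: np.ndarray = field(repr=False, default=None)
    fp: np.ndarray = field(repr=False, default=None)
    n_pos: int = 0
    n_neg: int = 0


def roc_curve(data: LabeledScores) -> RocCurve:
    """Empirical ROC curve under the "predict positive iff score >= t" rule.

    One curve point per distinct score value (ties share a threshold; no
    interpolation within ties), plus the (0, 0) corner.  The curve starts
    at (0, 0) and ends at (1, 1) and both rates are non-decreasing.
    """
    data._require_both_classes()
    order = np.argsort(data.scores)[::-1]
    s = data.scores[order]
    y = data.labels[order]
    distinct = np.r_[True, s[1:] != s[:-1]]
    # Cumulative positive/negative counts at each distinct threshold.
    cum_pos = np.cumsum(y)
    cum_neg = np.cumsum(~y)
    last_of_block = np.r_[distinct[1:], True]
    tp = np.r_[0, cum_pos[last_of_block]]
    fp = np.r_[0, cum_neg[last_of_block]]
    uniq = s[distinct]  # descending distinct scores
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.r_[np.inf, mids, -np.inf]
    n_pos, n_neg = data.n_pos, data.n_neg
    return RocCurve(
        thresholds=thresholds,
        tpr=tp / n_pos,
        fpr=fp / n_neg,
        tp=tp.astype(np.int64),
        fp=fp.astype(np.int64),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Equals the rank statistic P(score_pos > score_neg) + 0.5 * P(tie) on
    the underlying data.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_optimal(curve: RocCurve) -> tuple[float, float, float, float]:
    """The cut maximising J = TPR - FPR; ties break toward the larger threshold.

    Returns ``(threshold, tpr, fpr, J)``.  J is computed from integer
    counts as (tp*n_neg - fp*n_pos) / (n_pos*n_neg), the same arithmetic
    ``ks_two_sample`` uses, so the two statistics agree exactly.
    """
    j_num = curve.tp * curve.n_neg - curve.fp * curve.n_pos
    i = int(np.argmax(j_num))  # thresholds descend, so argmax's first hit is the largest cut
    j = float(j_num[i]) / (curve.n_pos * curve.n_neg)
    return (float(curve.thresholds[i]), float(curve.tpr[i]), float(curve.fpr[i]), j)


@dataclass(frozen=True)
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions."""

    d_stat: float
    at_score: float
    p_value: float


def _kolmogorov_sf(lam: float, terms: int = 101) -> float:
    """Asymptotic Kolmogorov survival function Q(lam) = 2*sum (-1)^(k-1) exp(-2 k^2 lam^2)."""
    if lam <= 0:
        return 1.0
    k = np.arange(1, terms)
    q = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * lam**2))
    return float(min(max(q, 0.0), 1.0))


def ks_two_sample(neg_scores: Sequence[float], pos_scores: Sequence[float]) -> KsResult:
    """Signed two-sample KS statistic D = max(ECDF_neg - ECDF_pos).

    The ECDFs use the <= convention; the signed difference (negative-class
    ECDF minus positive-class ECDF), not its absolute value, is maximised.
    Under the shared score >= threshold classification rule this equals the
    maximum Youden index of the same data.  ``at_score`` is the (largest,
    on ties) observed score where the maximum occurs.  The p-value uses the
    asymptotic two-sample formula.
    """
    neg = np.asarray(list(neg_scores), dtype=float)
    pos = np.asarray(list(pos_scores), dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ComputationError("both score lists must be non-empty")
    if not (np.all(np.isfinite(neg)) and np.all(np.isfinite(pos))):
        raise ValidationError("scores must be finite")
    values = np.unique(np.concatenate([neg, pos]))
    cn = np.searchsorted(np.sort(neg), values, side="right")
    cp = np.searchsorted(np.sort(pos), values, side="right")
    n_neg, n_pos = neg.size, pos.size
    d_num = cn * n_pos - cp * n_neg
    i = int(np.flatnonzero(d_num == d_num.max())[-1])
    d = float(d_num[i]) / (n_pos * n_neg)
    en = math.sqrt(n_neg * n_pos / (n_neg + n_pos))
    return KsResult(d_stat=d, at_score=float(values[i]), p_value=_kolmogorov_sf(en * d))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts and derived rates at one threshold.

    A rate whose denominator is zero is ``None`` (explicitly undefined),
    never silently 0 or NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _rate(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_at(data: LabeledScores, threshold: float) -> ConfusionSummary:
    """Confusion counts and rates for the rule "positive iff score >= threshold"."""
    pred = data.scores >= threshold
    tp = int(np.sum(pred & data.labels))
    fp = int(np.sum(pred & ~data.labels))
    fn = int(np.sum(~pred & data.labels))
    tn = int(np.sum(~pred & ~data.labels))
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_rate(tp + tn, tp + fp + tn + fn),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def metric_curves(data: LabeledScores) -> pd.DataFrame:
    """Confusion metrics at every distinct observed score threshold.

    Returns a tidy table (one row per distinct score, descending) with
    columns threshold, tp, fp, tn, fn, accuracy, sensitivity,
    specificity, ppv, npv — suitable for plotting predictive-value and
    accuracy curves.
    """
    thresholds = np.unique(data.scores)[::-1]
    rows = []
    for t in thresholds:
        c = confusion_at(data, t)
        rows.append(
            {
                "threshold": float(t),
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "accuracy": c.accuracy,
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
                "ppv": c.ppv,
                "npv": c.npv,
            }
        )
    return pd.DataFrame(rows)
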