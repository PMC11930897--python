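"""Diagnostic-accuracy statistics for binary and ordinal classifiers.

Covers the full evaluation toolkit used for the risk-stratification
comparison: confusion-matrix panels (recall, precision, accuracy, F1,
F-beta, Matthews correlation), the tie-corrected Mann-Whitney AUC of an
ordinal score with DeLong structural-component variance, the paired DeLong
test for correlated AUCs, and the intraclass correlation ICC(2,1) for
inter-rater agreement on ordinal categories.

Conventions for degenerate inputs are explicit: an MCC denominator of zero
yields MCC = 0; a recall or precision with an empty denominator is reported
as ``None`` (flagged), never silently 0; perfect-agreement but zero-variance
rating matrices give ICC = 1 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ContractError, DegenerateInputError

__all__ = [
    "ConfusionMatrix",
    "MetricPanel",
    "AucResult",
    "DeLongResult",
    "confusion_matrix",
    "panel_from_cm",
    "ordinal_auc",
    "delong_paired_test",
    "icc_absolute_agreement",
    "pct",
]


def pct(fraction: float | None, digits: int = 1) -> float | None:
    """Render a fraction as a percentage rounded half-up to ``digits``.

    Display-only: all metric arithmetic uses the unrounded fractions.
    """
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(fraction) * 100.0)).quantize(q, ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive = predicted invasive, true = pathology
    confirmed invasive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ContractError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricPanel:
    recall: float | None
    precision: float | None
    accuracy: float
    f1: float | None
    f_weighted: float | None
    beta: float
    mcc: float
    flags: tuple[str, ...] = field(default=(), compare=False)


def confusion_matrix(predictions, labels) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel boolean sequences."""
    preds = np.asarray(predictions, dtype=bool)
    labs = np.asarray(labels, dtype=bool)
    if preds.shape != labs.shape or preds.ndim != 1:
        raise ContractError(
            f"predictions and labels must be equal-length 1-D sequences, "
            f"got shapes {preds.shape} and {labs.shape}"
        )
    if preds.size == 0:
        raise ContractError("empty prediction/label sequences")
    return ConfusionMatrix(
        tp=int(np.sum(preds & labs)),
        fp=int(np.sum(preds & ~labs)),
        fn=int(np.sum(~preds & labs)),
        tn=int(np.sum(~preds & ~labs)),
    )


def panel_from_cm(cm: ConfusionMatrix, beta: float = 0.5) -> MetricPanel:
    """All confusion-matrix metrics from exact cell fractions.

    F_beta = (1 + beta^2) P R / (beta^2 P + R); beta < 1 weights precision,
    beta > 1 weights recall. MCC with a zero denominator is 0 by convention.
    """
    if beta <= 0:
        raise ContractError(f"beta must be > 0, got {beta}")
    if cm.total == 0:
        raise ContractError("confusion matrix has zero total")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    flags: list[str] = []

    recall = tp / (tp + fn) if tp + fn > 0 else None
    if recall is None:
        flags.append("recall undefined: no positive labels (TP+FN=0)")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    if precision is None:
        flags.append("precision undefined: no positive predictions (TP+FP=0)")
    accuracy = (tp + tn) / cm.total

    if recall is None or precision is None:
        f1 = f_weighted = None
        flags.append("F scores undefined")
    elif precision + recall == 0:
        f1 = f_weighted = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
        b2 = beta * beta
        f_weighted = (1 + b2) * precision * recall / (b2 * precision + recall)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("MCC denominator zero; MCC=0 by convention")
    else:
        mcc = (tp * tn - fp * fn) / float(np.sqrt(denom))

    return MetricPanel(
        recall=recall,
        precision=precision,
        accuracy=accuracy,
        f1=f1,
        f_weighted=f_weighted,
        beta=float(beta),
        mcc=mcc,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance_diff: float
    z: float
    p_two_sided: float


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ContractError("scores and labels must be equal-length 1-D sequences")
    if not (y.any() and (~y).any()):
        raise DegenerateInputError(
            "ROC undefined: labels contain a single class only"
        )
    return s, y


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (placement values).

    For each positive, the fraction of negatives scoring strictly below it
    plus half the ties; symmetrically for negatives. Midranks give both in
    O(n log n). mean(V10) is the tie-corrected Mann-Whitney AUC.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    rank_all = rankdata(np.concatenate([pos, neg]))
    v10 = (rank_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (rank_all[m:] - rankdata(neg)) / m
    return v10, v01


def ordinal_auc(scores, labels, level: float = 0.95) -> AucResult:
    """Tie-corrected Mann-Whitney AUC of an ordinal score.

    Equals the mean over all (positive, negative) pairs of 1 if the positive
    outranks the negative, 0.5 on ties, 0 otherwise. Variance from the
    DeLong structural components; CI by normal approximation, truncated to
    [0, 1].
    """
    s, y = _check_scores_labels(scores, labels)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    return AucResult(
        auc=auc,
        variance=var,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        level=level,
    )


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for two correlated AUCs evaluated on the same subjects.

    The variance of the AUC difference includes the covariance of the two
    sets of placement values; z = diff / sqrt(var), two-sided normal p. A
    zero-variance difference of exactly 0 (e.g. identical scores) reports
    p = 1.
    """
    sa, y = _check_scores_labels(scores_a, labels)
    sb, yb = _check_scores_labels(scores_b, labels)
    if sa.shape != sb.shape:
        raise ContractError("scores_a and scores_b must have equal length")
    v10a, v01a = _placements(sa, y)
    v10b, v01b = _placements(sb, yb)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    diff = auc_a - auc_b

    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    var_diff = max(var_diff, 0.0)

    if var_diff == 0.0:
        z = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / float(np.sqrt(var_diff))
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        difference=diff,
        variance_diff=var_diff,
        z=z,
        p_two_sided=p,
    )


def icc_absolute_agreement(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix of ordinal category
    codes. Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, rater and residual mean squares. An
    all-identical matrix (zero total variance) returns 1 by convention.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ContractError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ContractError(f"need >=2 subjects and >=2 raters, got {n}x{k}")
    if np.isnan(x).any():
        raise ContractError("ratings matrix has missing cells; complete design required")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        # all cells identical: perfect (if vacuous) agreement
        return 1.0
    return float((msr - mse) / denom)
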