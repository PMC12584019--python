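"""Binary-classification metric core.

Confusion matrices at an integer threshold, sensitivity / specificity /
accuracy / Youden index, AUC, and Youden-optimal cutoff search over the full
0–300 ClinFIT scale.

Conventions
-----------
* Positive prediction means ``score >= cutoff`` (the higher-intensity class
  sits at the high-impairment end of the scale), so sensitivity is
  non-increasing and specificity non-decreasing in the cutoff.
* Candidate cutoffs are the 301 integers 0..300 — ClinFIT totals are integer
  sums — not observed-score midpoints.
* Ties in the Youden index are broken toward the smallest cutoff.
* Metrics that are undefined (a class is empty) raise
  :class:`~clinstage.errors.UndefinedMetricError`; they are never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import SCORE_MAX, SCORE_MIN
from .errors import UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "CutoffMetrics",
    "confusion_at_cutoff",
    "metrics_from_confusion",
    "auc",
    "optimal_cutoff_youden",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for one cutoff on one binary comparison."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CutoffMetrics:
    """Diagnostic performance of one integer cutoff.

    ``youden == sensitivity + specificity - 1`` holds exactly (before any
    presentation rounding). ``auc`` is the area under the full ROC curve of
    the comparison the cutoff was derived on; ``n`` the sample size used.
    """

    cutoff: int
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    auc: float
    n: int


def _check_pair(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores)
    y = np.asarray(labels, dtype=bool)
    if s.ndim != 1 or y.ndim != 1:
        raise ValueError("scores and labels must be one-dimensional")
    if s.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {s.shape[0]} scores vs {y.shape[0]} labels")
    if s.shape[0] == 0:
        raise ValueError("empty input")
    return s, y


def confusion_at_cutoff(scores, labels, cutoff: int) -> ConfusionMatrix:
    """Confusion matrix with positives predicted where ``score >= cutoff``.

    ``labels`` is truthy for the higher-intensity (positive) class.
    """
    s, y = _check_pair(scores, labels)
    pred = s >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Se, Sp, accuracy and Youden index from raw counts.

    Raises :class:`UndefinedMetricError` when either true class is empty.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if neg == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    se = cm.tp / pos
    sp = cm.tn / neg
    return {
        "sensitivity": se,
        "specificity": sp,
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "youden": se + sp - 1.0,
    }


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann–Whitney probability ``P(score_pos > score_neg) +
    0.5 * P(tie)``, i.e. the trapezoidal area under the all-thresholds ROC
    curve. Both classes must be present.
    """
    s, y = _check_pair(scores, labels)
    if y.all() or (~y).all():
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(roc_auc_score(y, s))


def optimal_cutoff_youden(
    scores,
    labels,
    excluded_candidates: frozenset[int] | set[int] | None = None,
) -> CutoffMetrics:
    """Youden-optimal integer cutoff over the whole 0–300 scale.

    Evaluates every integer cutoff, returns the maximizer of
    ``sensitivity + specificity - 1``; ties go to the smallest cutoff.
    ``excluded_candidates`` removes specific values from the search (used for
    audited manual overrides in subgroup analyses).
    """
    s, y = _check_pair(scores, labels)
    if y.all() or (~y).all():
        raise UndefinedMetricError("cutoff search undefined: only one class present")
    if s.min() < SCORE_MIN or s.max() > SCORE_MAX:
        raise ValueError(f"scores outside [{SCORE_MIN}, {SCORE_MAX}]")

    n_cand = SCORE_MAX - SCORE_MIN + 2  # cutoffs 0..300 plus padding bin
    pos_hist = np.bincount(s[y], minlength=n_cand)
    neg_hist = np.bincount(s[~y], minlength=n_cand)
    # tail[c] = number of scores >= c, for c = 0..300
    tail_pos = pos_hist[::-1].cumsum()[::-1][: SCORE_MAX + 1]
    tail_neg = neg_hist[::-1].cumsum()[::-1][: SCORE_MAX + 1]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    # exact integer Youden numerator: J * n_pos * n_neg — float arithmetic
    # would break ties between mathematically equal cutoffs
    j_num = tail_pos.astype(np.int64) * n_neg - tail_neg.astype(np.int64) * n_pos
    if excluded_candidates:
        for c in excluded_candidates:
            if SCORE_MIN <= c <= SCORE_MAX:
                j_num[c] = np.iinfo(np.int64).min
    best = int(np.argmax(j_num))  # argmax returns the first (smallest) maximizer
    cm = confusion_at_cutoff(s, y, best)
    m = metrics_from_confusion(cm)
    return CutoffMetrics(
        cutoff=best,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        youden=m["youden"],
        auc=auc(s, y),
        n=int(s.shape[0]),
    )
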