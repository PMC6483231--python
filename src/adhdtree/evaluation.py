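"""Clinical-style evaluation: confusion matrix, accuracy, specificity, sensitivity.

ADHD is the positive class throughout.  Accuracy A = (TP+TN)/total,
specificity tn = TN/(TN+FP) (the true-negative rate over healthy subjects)
and sensitivity tp = TP/(TP+FN) (the true-positive rate over pathological
subjects) are reported as percentages; display rounding is to one decimal,
with unrounded values retained.  A rate whose denominator is zero is
undefined (None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_io import CohortError, DIAGNOSES


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise CohortError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        """Number of truly ADHD subjects."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Number of truly TD subjects."""
        return self.tn + self.fp


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float  # percent, unrounded
    specificity: float  # percent or None
    sensitivity: float  # percent or None

    def rounded(self) -> dict:
        """One-decimal display values (the precision used for reporting)."""
        rnd = lambda v: None if v is None else round(v, 1)
        return {
            "accuracy": rnd(self.accuracy),
            "specificity": rnd(self.specificity),
            "sensitivity": rnd(self.sensitivity),
        }

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "TP": self.confusion.tp,
                "TN": self.confusion.tn,
                "FP": self.confusion.fp,
                "FN": self.confusion.fn,
            },
            "accuracy_pct": self.accuracy,
            "specificity_pct": self.specificity,
            "sensitivity_pct": self.sensitivity,
            "display": self.rounded(),
        }


def confusion(predicted, true) -> ConfusionMatrix:
    """Count prediction outcomes; ADHD is the positive class."""
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise CohortError(
            f"length mismatch: {len(predicted)} predictions vs {len(true)} labels"
        )
    if not true:
        raise CohortError("confusion needs at least one subject")
    for lab in predicted + true:
        if lab not in DIAGNOSES:
            raise CohortError(f"invalid label {lab!r}")
    tp = sum(p == "ADHD" and t == "ADHD" for p, t in zip(predicted, true))
    tn = sum(p == "TD" and t == "TD" for p, t in zip(predicted, true))
    fp = sum(p == "ADHD" and t == "TD" for p, t in zip(predicted, true))
    fn = sum(p == "TD" and t == "ADHD" for p, t in zip(predicted, true))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def summarize(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy / specificity / sensitivity (percent) from a confusion matrix."""
    if cm.total < 1:
        raise CohortError("cannot summarize an empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    specificity = 100.0 * cm.tn / cm.n_negative if cm.n_negative else None
    sensitivity = 100.0 * cm.tp / cm.n_positive if cm.n_positive else None
    return EvalReport(
        confusion=cm, accuracy=accuracy, specificity=specificity, sensitivity=sensitivity
    )


def evaluate(predicted, true) -> EvalReport:
    return summarize(confusion(predicted, true))


def format_confusion_table(cm: ConfusionMatrix) -> str:
    """Plain-text confusion table: rows = true class, columns = predicted."""
    lines = [
        "Predicted as >   TD  ADHD",
        f"TD             {cm.tn:4d}  {cm.fp:4d}",
        f"ADHD           {cm.fn:4d}  {cm.tp:4d}",
    ]
    return "\n".join(lines)
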