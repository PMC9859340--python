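"""Three-class confusion matrix and micro/macro evaluation metrics.

Implemented from first principles (no delegation) so the evaluation
protocol is self-contained and auditable.  Conventions: rows of the
confusion matrix are actual classes, columns are predicted classes.
For class i, TP_i is the diagonal count, FP_i the rest of column i
(other classes predicted as i) and FN_i the rest of row i.

In single-label multi-class classification the micro-averaged
precision, recall and F1 coincide with each other and with overall
accuracy (the diagonal sum over the total), so the macro averages are
the informative companions.  A literal variant of the overall-accuracy
formula that double-counts errors in the denominator is provided as
:func:`accuracy_error_normalized` for comparison; :func:`accuracy` is
the standard diagonal-over-total definition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import UndefinedMetricError
from .labeling import CLASS_NAMES

N_CLASSES = 3


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 integer counts; rows = actual class, columns = predicted class."""

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (N_CLASSES, N_CLASSES) or np.any(arr < 0):
            raise ValueError("confusion matrix must be 3x3 with nonnegative counts")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.array.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.array)

    def fp(self) -> np.ndarray:
        """Per-class false positives: column sum minus the diagonal."""
        a = self.array
        return a.sum(axis=0) - np.diag(a)

    def fn(self) -> np.ndarray:
        """Per-class false negatives: row sum minus the diagonal."""
        a = self.array
        return a.sum(axis=1) - np.diag(a)

    def __str__(self) -> str:
        a = self.array
        head = "actual\\predicted  " + "  ".join(f"{c:>6}" for c in CLASS_NAMES)
        rows = [
            f"{CLASS_NAMES[i]:>16}  " + "  ".join(f"{a[i, j]:>6d}" for j in range(3))
            for i in range(3)
        ]
        return "\n".join([head] + rows)


def confusion_matrix(actual: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix3:
    """Tally a 3-class confusion matrix from integer labels 0/1/2."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be 1-D of equal length")
    if a.size == 0:
        raise ValueError("need at least one label pair")
    if np.any((a < 0) | (a >= N_CLASSES)) or np.any((p < 0) | (p >= N_CLASSES)):
        raise ValueError("labels must be integers in {0, 1, 2}")
    m = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for ai, pi in zip(a, p):
        m[ai, pi] += 1
    return ConfusionMatrix3(tuple(tuple(int(v) for v in row) for row in m))


def _check_nonempty(cm: ConfusionMatrix3) -> None:
    if cm.total == 0:
        raise UndefinedMetricError("metrics undefined for an empty confusion matrix")


def accuracy(cm: ConfusionMatrix3) -> float:
    """Overall accuracy: correctly classified share (diagonal over total)."""
    _check_nonempty(cm)
    return float(cm.tp().sum() / cm.total)


def accuracy_error_normalized(cm: ConfusionMatrix3) -> float:
    """Sum TP / (sum TP + sum FP + sum FN): each error counted twice.

    Kept only for comparison with :func:`accuracy`; equals it iff the
    matrix is diagonal.
    """
    _check_nonempty(cm)
    tp, fp, fn = cm.tp().sum(), cm.fp().sum(), cm.fn().sum()
    return float(tp / (tp + fp + fn))


def micro_metrics(cm: ConfusionMatrix3) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1).

    All three equal the diagonal sum divided by the total in the
    single-label setting, hence equal :func:`accuracy`.
    """
    _check_nonempty(cm)
    tp, fp, fn = cm.tp().sum(), cm.fp().sum(), cm.fn().sum()
    mi_p = tp / (tp + fp)
    mi_r = tp / (tp + fn)
    if mi_p == mi_r:  # always true here; keeps the identity exact
        mi_f1 = mi_p
    else:
        mi_f1 = 2 * mi_p * mi_r / (mi_p + mi_r) if (mi_p + mi_r) > 0 else 0.0
    return float(mi_p), float(mi_r), float(mi_f1)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    ok = den > 0
    if not np.any(ok):
        raise UndefinedMetricError(f"all per-class {what} denominators are zero")
    if not np.all(ok):
        warnings.warn(
            f"class(es) {np.flatnonzero(~ok).tolist()} have zero {what} "
            "denominator and contribute 0 to the macro average",
            stacklevel=3,
        )
    out[ok] = num[ok] / den[ok]
    return out


def macro_metrics(cm: ConfusionMatrix3) -> tuple[float, float, float]:
    """Macro-averaged (precision, recall, F1): unweighted mean over classes.

    Classes that are never predicted (zero precision denominator) or
    never occur (zero recall denominator) contribute 0 with a warning.
    """
    _check_nonempty(cm)
    tp, fp, fn = cm.tp(), cm.fp(), cm.fn()
    prec = _safe_ratio(tp.astype(float), (tp + fp).astype(float), "precision")
    rec = _safe_ratio(tp.astype(float), (tp + fn).astype(float), "recall")
    ma_p = float(prec.mean())
    ma_r = float(rec.mean())
    ma_f1 = 2 * ma_p * ma_r / (ma_p + ma_r) if (ma_p + ma_r) > 0 else 0.0
    return ma_p, ma_r, float(ma_f1)


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation report for one test set."""

    acc: float
    mi_p: float
    mi_r: float
    mi_f1: float
    ma_p: float
    ma_r: float
    ma_f1: float

    METRIC_FIELDS = ("acc", "mi_p", "mi_r", "mi_f1", "ma_p", "ma_r", "ma_f1")

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix3) -> "MetricsReport":
        mi = micro_metrics(cm)
        ma = macro_metrics(cm)
        return cls(accuracy(cm), *mi, *ma)

    @classmethod
    def from_predictions(cls, actual, predicted) -> "MetricsReport":
        return cls.from_confusion(confusion_matrix(actual, predicted))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.METRIC_FIELDS])

    @classmethod
    def from_array(cls, values) -> "MetricsReport":
        return cls(*(float(v) for v in values))
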