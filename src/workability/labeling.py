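"""Quartile-based three-stage health classes from grade sums.

Subjects are ranked by their fuzzy grade sum and split at the first and
third quartiles of the cohort: C1 (grade below Q1) marks poor health,
C2 (between Q1 and Q3) moderate, and C3 (at or above Q3) good health.
Quartiles are located at ranks (n+1)/4 and 3(n+1)/4 of the sorted
grades, with linear interpolation between order statistics.  Classes
are cohort-relative by design: there is no external clinical cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import SUBSYSTEMS
from .errors import SampleSizeError

CLASS_NAMES = ("C1", "C2", "C3")


@dataclass(frozen=True)
class QuartileSplit:
    """Summary of a cohort's grade distribution used for class assignment."""

    n: int
    min: float
    max: float
    q1: float
    q3: float


def _rank_value(sorted_grades: np.ndarray, rank: float) -> float:
    # 1-based rank with linear interpolation, clamped to the sample
    n = sorted_grades.size
    rank = min(max(rank, 1.0), float(n))
    lo = int(np.floor(rank))
    frac = rank - lo
    if frac == 0.0 or lo >= n:
        return float(sorted_grades[lo - 1])
    return float(
        sorted_grades[lo - 1] + frac * (sorted_grades[lo] - sorted_grades[lo - 1])
    )


def quartile_split(grades: Sequence[float]) -> QuartileSplit:
    """First and third quartiles of the grades at ranks (n+1)/4 and 3(n+1)/4."""
    g = np.asarray(grades, dtype=float)
    n = g.size
    if n < 4:
        raise SampleSizeError(f"quartile split needs at least 4 subjects, got {n}")
    s = np.sort(g)
    q1 = _rank_value(s, (n + 1) / 4.0)
    q3 = _rank_value(s, 3.0 * (n + 1) / 4.0)
    return QuartileSplit(n=n, min=float(s[0]), max=float(s[-1]), q1=q1, q3=q3)


def assign_class(grade: float, split: QuartileSplit) -> int:
    """Class of one grade: 0 (C1) below Q1, 1 (C2) in [Q1, Q3), 2 (C3) at/above Q3.

    Grades outside the training range are clamped to the nearest class
    by the same rule, so out-of-cohort subjects still receive a label.
    """
    if grade < split.q1:
        return 0
    if grade < split.q3:
        return 1
    return 2


class QuartileLabeler(BaseEstimator):
    """Cohort-relative health-class labeler (scikit-learn estimator).

    ``fit`` memorizes the quartile split of the training grades;
    ``predict`` maps grades to integer classes 0/1/2 (C1/C2/C3).
    """

    def fit(self, X, y=None):
        grades = np.asarray(X, dtype=float).ravel()
        split = quartile_split(grades)
        if split.q1 == split.q3:
            warnings.warn(
                "degenerate quartile split (Q1 == Q3): every subject at or "
                "above Q3 is labeled C3",
                stacklevel=2,
            )
        self.split_ = split
        self.q1_, self.q3_ = split.q1, split.q3
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "split_")
        grades = np.asarray(X, dtype=float).ravel()
        out = np.ones(grades.size, dtype=int)
        out[grades < self.split_.q1] = 0
        out[grades >= self.split_.q3] = 2
        return out

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def label_cohort(scored: pd.DataFrame, per_system: bool = True) -> pd.DataFrame:
    """Label a scored cohort on its overall grade and, optionally, per subsystem.

    Parameters
    ----------
    scored : DataFrame
        Score table with grade-sum columns (``cardiovascular``,
        ``muscular``, ``nervous``, ``total``), as produced by
        :meth:`workability.FuzzyScorer.score_table`.
    per_system : bool
        When true, each subsystem's grade sums are quartile-split
        independently, yielding one label vector per subsystem in
        addition to the overall one.

    Returns
    -------
    DataFrame with integer label columns (``label_overall`` and
    ``label_<subsystem>``) plus matching ``class_*`` string columns.
    """
    out = pd.DataFrame(index=scored.index)
    targets = [("overall", "total")]
    if per_system:
        targets += [(s, s) for s in SUBSYSTEMS]
    for tag, column in targets:
        labels = QuartileLabeler().fit_predict(scored[column].to_numpy())
        out[f"label_{tag}"] = labels
        out[f"class_{tag}"] = [CLASS_NAMES[k] for k in labels]
    return out
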