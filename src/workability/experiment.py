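"""Repeated random-forest evaluation of the scored, labeled cohort.

Protocol: per iteration, a stratified 70/30 train/test split; a random
forest (entropy splits) fitted on the training part with a 5-fold
cross-validation score reported as an overfitting diagnostic; micro and
macro metrics computed on the held-out 30%.  The split and the forest
are re-randomized over 50 iterations (configurable) and the metrics are
arithmetically averaged.  Feature importances (mean decrease of the
entropy split criterion) below 0.05 are flagged as ignorable; the
filter is applied to the all-features model only — the per-subsystem
models keep their few features.

The forest itself is scikit-learn's ``RandomForestClassifier``;
everything around it (splitting protocol, metrics, averaging,
importance filtering) is implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold, cross_val_score, train_test_split

from .config import ExpertConfig, SUBSYSTEMS, default_config
from .errors import DegenerateLabelError
from .metrics import MetricsReport

TABLE_METRIC_LABELS = {
    "acc": "Accuracy, ACC",
    "mi_p": "Micro precision, mi P",
    "mi_r": "Micro recall, mi R",
    "mi_f1": "Micro F-1 score, mi F1",
    "ma_p": "Macro precision, ma P",
    "ma_r": "Macro recall, ma R",
    "ma_f1": "Macro F-1 score, ma F1",
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the repeated-split evaluation protocol."""

    train_fraction: float = 0.7
    n_iterations: int = 50
    cv_folds: int = 5
    importance_threshold: float = 0.05
    n_trees: int = 100
    criterion: str = "entropy"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.importance_threshold < 0:
            raise ValueError("importance_threshold must be nonnegative")
        if self.criterion not in ("entropy", "gini"):
            raise ValueError("criterion must be 'entropy' or 'gini'")


@dataclass
class TrainResult:
    """One fitted forest with its held-out metrics and diagnostics."""

    model: RandomForestClassifier
    report: MetricsReport
    importances: pd.Series
    cv_scores: np.ndarray

    @property
    def cv_mean(self) -> float:
        return float(self.cv_scores.mean())


@dataclass
class ExperimentResult:
    """Aggregate of the repeated-split protocol for one feature set."""

    reports: list[MetricsReport]
    averaged: MetricsReport
    mean_importances: pd.Series
    retained: list[str]
    cv_means: list[float]
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "averaged": self.averaged.to_dict(),
            "per_iteration": [r.to_dict() for r in self.reports],
            "mean_importances": {
                k: float(v) for k, v in self.mean_importances.items()
            },
            "retained_features": list(self.retained),
            "cv_means": [float(v) for v in self.cv_means],
            "feature_names": list(self.feature_names),
        }


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(np.asarray(features))


def train_once(
    features,
    labels: Sequence[int],
    cfg: TrainConfig = TrainConfig(),
    seed: int | None = None,
) -> TrainResult:
    """One stratified 70/30 split, forest fit, CV diagnostic and test report."""
    X = _as_frame(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 subjects, got {X.shape[0]}")
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelError("labels contain a single class")
    seed = cfg.seed if seed is None else seed

    stratify = y
    if class_counts.min() < 2:
        warnings.warn(
            "a class has fewer than 2 members; falling back to an "
            "unstratified split",
            stacklevel=2,
        )
        stratify = None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=cfg.train_fraction, random_state=seed, stratify=stratify
    )

    model = RandomForestClassifier(
        n_estimators=cfg.n_trees, criterion=cfg.criterion, random_state=seed
    )

    # cross-validation on the training part: overfitting diagnostic only
    min_train_class = np.unique(y_tr, return_counts=True)[1].min()
    n_folds = min(cfg.cv_folds, int(min_train_class))
    if n_folds >= 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        cv_scores = cross_val_score(model, X_tr, y_tr, cv=cv)
    else:
        cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
        cv_scores = cross_val_score(model, X_tr, y_tr, cv=cv)

    model.fit(X_tr, y_tr)
    report = MetricsReport.from_predictions(y_te, model.predict(X_te))
    importances = pd.Series(model.feature_importances_, index=X.columns)
    return TrainResult(model=model, report=report,
                       importances=importances, cv_scores=np.asarray(cv_scores))


def run_experiment(
    features,
    labels: Sequence[int],
    cfg: TrainConfig = TrainConfig(),
) -> ExperimentResult:
    """Repeat :func:`train_once` over independent splits and average.

    Iteration seeds are derived deterministically from ``cfg.seed``, so
    the whole experiment is a pure function of (features, labels, cfg).
    """
    X = _as_frame(features)
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_iterations)
    reports, importances, cv_means = [], [], []
    for s in child_seeds:
        res = train_once(X, labels, cfg, seed=int(s % (2**31 - 1)))
        reports.append(res.report)
        importances.append(res.importances)
        cv_means.append(res.cv_mean)
    averaged = MetricsReport.from_array(
        np.mean([r.as_array() for r in reports], axis=0)
    )
    mean_imp = pd.concat(importances, axis=1).mean(axis=1)
    return ExperimentResult(
        reports=reports,
        averaged=averaged,
        mean_importances=mean_imp,
        retained=list(X.columns),
        cv_means=cv_means,
        feature_names=list(X.columns),
    )


def importance_filter(
    importances: Mapping[str, float], threshold: float = 0.05
) -> list[str]:
    """Names of features whose mean importance reaches the threshold.

    Input order is preserved.  If no feature qualifies, all are kept
    (with a warning): a model cannot be trained on zero features.
    """
    items = list(importances.items())
    if any(v < 0 for _, v in items):
        raise ValueError("importances must be nonnegative")
    retained = [k for k, v in items if v >= threshold]
    if not retained:
        warnings.warn(
            "no feature reaches the importance threshold; keeping all",
            stacklevel=2,
        )
        return [k for k, _ in items]
    return retained


def run_three_system_evaluation(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    cfg: TrainConfig = TrainConfig(),
    config: ExpertConfig | None = None,
) -> dict[str, ExperimentResult]:
    """The full step-3 evaluation: all-features model plus one per subsystem.

    Parameters
    ----------
    scores : DataFrame
        Per-feature crisp scores (21 columns for the default battery).
    labels : DataFrame
        Output of :func:`workability.labeling.label_cohort` with
        ``label_overall`` and per-subsystem label columns.
    cfg : TrainConfig
        Shared protocol configuration.
    config : ExpertConfig, optional
        Feature/subsystem layout (bundled default if omitted).

    The all-features experiment additionally reports which features
    survive the importance filter; subsystem experiments keep all their
    features.
    """
    config = config if config is not None else default_config()
    results: dict[str, ExperimentResult] = {}

    all_feats = config.feature_names
    res_all = run_experiment(scores[all_feats], labels["label_overall"], cfg)
    res_all.retained = importance_filter(
        res_all.mean_importances, cfg.importance_threshold
    )
    results["all_features"] = res_all

    for subsystem in SUBSYSTEMS:
        feats = config.subsystem_index[subsystem]
        label_col = f"label_{subsystem}"
        if label_col not in labels:
            raise KeyError(
                f"labels lack {label_col!r}; run label_cohort(per_system=True)"
            )
        results[subsystem] = run_experiment(
            scores[feats], labels[label_col], cfg
        )
    return results


def comparison_table(results: Mapping[str, ExperimentResult]) -> pd.DataFrame:
    """Averaged metrics, one column per experiment, one row per metric."""
    cols = {}
    for name, res in results.items():
        d = res.averaged.to_dict()
        cols[name] = [d[k] for k in MetricsReport.METRIC_FIELDS]
    return pd.DataFrame(
        cols,
        index=[TABLE_METRIC_LABELS[k] for k in MetricsReport.METRIC_FIELDS],
    )


def results_to_json(results: Mapping[str, ExperimentResult], **kwargs) -> str:
    kwargs.setdefault("sort_keys", True)
    kwargs.setdefault("indent", 2)
    return json.dumps({k: v.to_dict() for k, v in results.items()}, **kwargs)
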