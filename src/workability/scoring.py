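"""Cohort-level fuzzy scoring as a scikit-learn transformer."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .config import ExpertConfig, default_config, derive_features_frame
from .errors import MissingFeatureError
from .fuzzy import build_fuzzy_features, score_feature

SUM_COLUMNS = ("cardiovascular", "muscular", "nervous", "total")


class FuzzyScorer(BaseEstimator, TransformerMixin):
    """Transform raw physiological measurements into crisp 1–5 scores.

    Fitting estimates the transition-zone halfwidths from the cohort
    (half the standard deviation of the values in the bin above each
    expert threshold); transforming evaluates the weighted-average fuzzy
    inference per feature.  A scorer can therefore be fitted on a
    reference cohort once and applied to new subjects.

    Parameters
    ----------
    config : ExpertConfig, optional
        Expert threshold configuration; the bundled 21-feature battery
        by default.
    halfwidths : {"auto", "default", "crisp"}, float or mapping
        ``"auto"`` estimates halfwidths from the fitted cohort (falling
        back to config defaults for sparse bins); ``"default"`` always
        uses the config defaults; ``"crisp"`` disables transition zones
        entirely (pure table lookup); a float applies one halfwidth to
        every threshold; a mapping overrides per feature.
    min_bin_count : int
        Minimum subjects per threshold bin for a spread estimate.

    Attributes
    ----------
    fuzzy_features_ : dict
        Feature name -> assembled :class:`~workability.fuzzy.FuzzyFeature`.
    feature_names_in_ : ndarray of str
        Raw input columns seen during fit.
    """

    def __init__(self, config: ExpertConfig | None = None,
                 halfwidths="auto", min_bin_count: int = 2):
        self.config = config
        self.halfwidths = halfwidths
        self.min_bin_count = min_bin_count

    def _config(self) -> ExpertConfig:
        return self.config if self.config is not None else default_config()

    def _check_frame(self, X, config) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=config.raw_feature_names)
        missing = [c for c in config.raw_feature_names if c not in X.columns]
        if missing:
            raise MissingFeatureError(missing)
        return derive_features_frame(X[config.raw_feature_names], config)

    def fit(self, X, y=None):
        """Estimate transition halfwidths from a raw-feature cohort."""
        config = self._config()
        frame = self._check_frame(X, config)
        hw = self.halfwidths
        if isinstance(hw, str):
            if hw == "auto":
                self.fuzzy_features_ = build_fuzzy_features(
                    config, frame, min_bin_count=self.min_bin_count
                )
            elif hw == "default":
                self.fuzzy_features_ = build_fuzzy_features(config)
            elif hw == "crisp":
                self.fuzzy_features_ = build_fuzzy_features(config, halfwidths=0.0)
            else:
                raise ValueError(
                    "halfwidths must be 'auto', 'default', 'crisp', a number "
                    f"or a mapping, got {hw!r}"
                )
        else:
            self.fuzzy_features_ = build_fuzzy_features(config, halfwidths=hw)
        self.config_ = config
        self.feature_names_in_ = np.asarray(config.raw_feature_names, dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-feature crisp scores (one column per battery feature)."""
        check_is_fitted(self, "fuzzy_features_")
        frame = self._check_frame(X, self.config_)
        out = {
            name: score_feature(frame[name].to_numpy(dtype=float),
                                self.fuzzy_features_[name])
            for name in self.config_.feature_names
        }
        return pd.DataFrame(out, index=frame.index)

    def score_table(self, X) -> pd.DataFrame:
        """Scores plus subsystem grade sums and the overall grade.

        Appends one column per subsystem (sum of its feature scores) and
        a ``total`` column (sum of all 21) to :meth:`transform`'s output.
        """
        scores = self.transform(X)
        return attach_grade_sums(scores, self.config_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "fuzzy_features_")
        return np.asarray(self.config_.feature_names, dtype=object)


def attach_grade_sums(scores: pd.DataFrame, config: ExpertConfig) -> pd.DataFrame:
    """Append per-subsystem and overall grade-sum columns to a score table."""
    out = scores.copy()
    for subsystem, names in config.subsystem_index.items():
        out[subsystem] = scores[names].sum(axis=1)
    out["total"] = scores[config.feature_names].sum(axis=1)
    return out
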