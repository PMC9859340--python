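"""Trapezoidal fuzzy membership functions and crisp 1–5 scoring.

Each physiological feature is partitioned by expert thresholds into 3 or
5 scored levels.  Raw measurements rarely respect hard cut-offs, so each
internal threshold ``t`` is surrounded by a *transition zone*
``[t - h, t + h]`` inside which the two adjacent levels overlap with
complementary linear ramps.  The halfwidth ``h`` is half the standard
deviation of the data adjacent to the threshold (a threshold of 25 with
adjacent-bin SD 8 yields a ramp drawn between 21 and 29); when no cohort
is available a per-feature default halfwidth from the configuration is
used instead.

The lowest level of a feature carries a *left* side curve (membership 1
below its threshold), the highest a *right* side curve, and interior
levels carry trapezia.  By construction the level memberships form a
partition of unity over the whole value domain, so the weighted-average
inference

    score(x) = sum_l mu_l(x) * score_l / sum_l mu_l(x)

returns the integer table score on every plateau and interpolates
linearly across transition zones.  Discrete count features (the four
static-balance mistake counts) use zero-width ramps, i.e. crisp steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import ExpertConfig, FeatureSpec, derive_features
from .errors import (
    ConfigError,
    DomainError,
    MissingFeatureError,
    ParameterError,
)

__all__ = [
    "trapezium_membership",
    "left_membership",
    "right_membership",
    "transition_zone",
    "MembershipCurve",
    "FuzzyFeature",
    "build_fuzzy_feature",
    "build_fuzzy_features",
    "estimate_threshold_sds",
    "score_feature",
    "ScoredRecord",
    "score_record",
]


# ---------------------------------------------------------------------------
# membership primitives
# ---------------------------------------------------------------------------

def trapezium_membership(x, a1: float, a2: float, a3: float, a4: float):
    """Trapezoidal membership: 0 outside [a1, a4), ramps up on [a1, a2),
    plateau 1 on [a2, a3), ramps down on [a3, a4).

    Zero-width ramps (equal knots) degenerate to steps; the half-open
    convention keeps adjacent curves complementary at the knot itself.
    """
    if not (a1 <= a2 <= a3 <= a4):
        raise ParameterError(f"unordered trapezium knots ({a1}, {a2}, {a3}, {a4})")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if a2 > a1:
        rising = (x >= a1) & (x < a2)
        out[rising] = (x[rising] - a1) / (a2 - a1)
    plateau = (x >= a2) & (x < a3)
    out[plateau] = 1.0
    if a4 > a3:
        falling = (x >= a3) & (x < a4)
        out[falling] = (x[falling] - a4) / (a3 - a4)
    return out if out.ndim else float(out)


def left_membership(x, b1: float, b2: float):
    """Left side curve: 1 below b1, linear descent on [b1, b2), 0 at and above b2."""
    if b1 > b2:
        raise ParameterError(f"unordered left-curve knots ({b1}, {b2})")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    out[x < b1] = 1.0
    if b2 > b1:
        ramp = (x >= b1) & (x < b2)
        out[ramp] = (x[ramp] - b2) / (b1 - b2)
    return out if out.ndim else float(out)


def right_membership(x, c1: float, c2: float):
    """Right side curve: 0 below c1, linear ascent on [c1, c2), 1 at and above c2.

    The mirror image of :func:`left_membership`; together they sum to 1
    at every point when their knots coincide.
    """
    if c1 > c2:
        raise ParameterError(f"unordered right-curve knots ({c1}, {c2})")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    out[x >= c2] = 1.0
    if c2 > c1:
        ramp = (x >= c1) & (x < c2)
        out[ramp] = (x[ramp] - c1) / (c2 - c1)
    return out if out.ndim else float(out)


def transition_zone(threshold: float, sd: float) -> tuple[float, float]:
    """Transition-zone edges around an internal threshold.

    The zone spans half the adjacent data's standard deviation on each
    side: SD 8 around threshold 25 gives the ramp interval (21, 29).
    """
    if sd < 0:
        raise ParameterError(f"negative standard deviation {sd}")
    h = sd / 2.0
    return threshold - h, threshold + h


# ---------------------------------------------------------------------------
# curve assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipCurve:
    """One membership curve attached to a score level."""

    shape: str  # 'trapezium' | 'left' | 'right'
    knots: tuple[float, ...]
    score: int

    def __post_init__(self):
        expected = {"trapezium": 4, "left": 2, "right": 2}
        if self.shape not in expected:
            raise ParameterError(f"unknown curve shape {self.shape!r}")
        if len(self.knots) != expected[self.shape]:
            raise ParameterError(
                f"{self.shape} curve needs {expected[self.shape]} knots"
            )

    def __call__(self, x):
        if self.shape == "trapezium":
            return trapezium_membership(x, *self.knots)
        if self.shape == "left":
            return left_membership(x, *self.knots)
        return right_membership(x, *self.knots)


@dataclass(frozen=True)
class FuzzyFeature:
    """A feature spec together with its assembled membership curves."""

    spec: FeatureSpec
    curves: tuple[MembershipCurve, ...]  # one per level, in level order
    halfwidths: tuple[float, ...]  # per internal threshold

    def memberships(self, x) -> np.ndarray:
        """Membership of ``x`` in every level (levels along the first axis)."""
        return np.stack([np.atleast_1d(np.asarray(c(x), dtype=float))
                         for c in self.curves])

    def score(self, x):
        return score_feature(x, self)


def _resolve_halfwidths(
    spec: FeatureSpec,
    threshold_sds,
    halfwidths,
) -> list[float]:
    thresholds = spec.internal_thresholds
    if spec.discrete:
        return [0.0] * len(thresholds)
    if halfwidths is not None:
        if np.isscalar(halfwidths):
            return [float(halfwidths)] * len(thresholds)
        return [float(halfwidths.get(t, spec.default_halfwidth)) for t in thresholds]
    if threshold_sds is not None:
        if np.isscalar(threshold_sds):
            threshold_sds = {t: threshold_sds for t in thresholds}
        out = []
        for t in thresholds:
            sd = threshold_sds.get(t)
            if sd is None:
                out.append(spec.default_halfwidth)
            else:
                if sd < 0:
                    raise ParameterError(f"{spec.name}: negative SD at threshold {t}")
                out.append(sd / 2.0)
        return out
    return [spec.default_halfwidth] * len(thresholds)


def build_fuzzy_feature(
    spec: FeatureSpec,
    threshold_sds: Mapping[float, float] | float | None = None,
    *,
    halfwidths: Mapping[float, float] | float | None = None,
) -> FuzzyFeature:
    """Assemble the membership curves of one feature.

    Parameters
    ----------
    spec : FeatureSpec
        Validated feature description (levels define the thresholds).
    threshold_sds : mapping threshold -> SD, or scalar, optional
        Standard deviation of the data adjacent to each internal
        threshold; the transition halfwidth is SD/2.  Thresholds absent
        from the mapping fall back to the spec's default halfwidth.
    halfwidths : mapping threshold -> halfwidth, or scalar, optional
        Direct halfwidth override (takes precedence over SDs).

    Transition zones are clipped so neighbouring zones never overlap
    (each halfwidth is capped at half the inter-threshold gap).  A zone
    that would still cross the value-domain boundary raises
    :class:`~workability.errors.ConfigError`.
    """
    thresholds = list(spec.internal_thresholds)
    h = _resolve_halfwidths(spec, threshold_sds, halfwidths)

    # clip so adjacent zones never overlap
    for i in range(len(thresholds) - 1):
        gap = thresholds[i + 1] - thresholds[i]
        h[i] = min(h[i], gap / 2.0)
        h[i + 1] = min(h[i + 1], gap / 2.0)

    lo, hi = spec.value_domain
    if thresholds and (thresholds[0] - h[0] < lo or thresholds[-1] + h[-1] > hi):
        raise ConfigError(
            f"{spec.name}: transition zone extends beyond the value domain"
        )

    curves = []
    for i, lv in enumerate(spec.levels):
        if i == 0:
            t = thresholds[0]
            curves.append(
                MembershipCurve("left", (t - h[0], t + h[0]), lv.score)
            )
        elif i == len(spec.levels) - 1:
            t = thresholds[-1]
            curves.append(
                MembershipCurve("right", (t - h[-1], t + h[-1]), lv.score)
            )
        else:
            tl, tr = thresholds[i - 1], thresholds[i]
            hl, hr = h[i - 1], h[i]
            curves.append(
                MembershipCurve(
                    "trapezium", (tl - hl, tl + hl, tr - hr, tr + hr), lv.score
                )
            )
    return FuzzyFeature(spec=spec, curves=tuple(curves), halfwidths=tuple(h))


def estimate_threshold_sds(
    values: Sequence[float], spec: FeatureSpec, *, min_bin_count: int = 2
) -> dict[float, float]:
    """Per-threshold SD estimates from cohort data.

    For each internal threshold the spread of the values falling in the
    level interval directly *above* it is used (sample SD, ddof=1).
    Thresholds whose upper bin holds fewer than ``min_bin_count`` values
    are omitted, so downstream construction falls back to the feature's
    default halfwidth.
    """
    v = np.asarray(values, dtype=float)
    out: dict[float, float] = {}
    thresholds = spec.internal_thresholds
    uppers = list(thresholds[1:]) + [spec.value_domain[1]]
    for t, u in zip(thresholds, uppers):
        in_bin = v[(v >= t) & (v < u)]
        if in_bin.size >= min_bin_count:
            out[t] = float(np.std(in_bin, ddof=1))
    return out


def build_fuzzy_features(
    config: ExpertConfig,
    cohort=None,
    *,
    halfwidths=None,
    min_bin_count: int = 2,
) -> dict[str, FuzzyFeature]:
    """Build fuzzy features for a whole configuration.

    When ``cohort`` (a DataFrame of raw + derived features) is given,
    transition halfwidths are estimated from the per-threshold data
    spread; otherwise the config defaults apply.  ``halfwidths`` may be
    a scalar applied everywhere or a mapping feature -> (scalar or
    threshold mapping) overriding the estimates.
    """
    out = {}
    for spec in config:
        hw = None
        if halfwidths is not None:
            hw = halfwidths if np.isscalar(halfwidths) else halfwidths.get(spec.name)
        sds = None
        if hw is None and cohort is not None and spec.name in cohort:
            sds = estimate_threshold_sds(
                cohort[spec.name].to_numpy(), spec, min_bin_count=min_bin_count
            )
        out[spec.name] = build_fuzzy_feature(spec, sds, halfwidths=hw)
    return out


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def score_feature(x, ff: FuzzyFeature):
    """Crisp 1–5 score by membership-weighted averaging of level scores."""
    lo, hi = ff.spec.value_domain
    xv = np.asarray(x, dtype=float)
    if np.any(xv < lo) or np.any(xv > hi):
        raise DomainError(
            f"{ff.spec.name}: value outside domain [{lo}, {hi}]"
        )
    mu = ff.memberships(xv)
    total = mu.sum(axis=0)
    if np.any(total <= 0):
        raise AssertionError(
            f"{ff.spec.name}: zero total membership (construction bug)"
        )
    scores = np.array([c.score for c in ff.curves], dtype=float)
    result = (mu * scores[:, None]).sum(axis=0) / total
    return float(result[0]) if np.ndim(x) == 0 else result


@dataclass(frozen=True)
class ScoredRecord:
    """Per-feature crisp scores with subsystem and overall grade sums."""

    feature_scores: dict[str, float]
    subsystem_sums: dict[str, float]
    total: float = field(default=0.0)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float], config: ExpertConfig):
        sums = {
            s: sum(scores[n] for n in names)
            for s, names in config.subsystem_index.items()
        }
        return cls(
            feature_scores=dict(scores),
            subsystem_sums=sums,
            total=sum(scores.values()),
        )


def score_record(
    record: Mapping[str, float],
    config: ExpertConfig,
    fuzzy: Mapping[str, FuzzyFeature] | None = None,
) -> ScoredRecord:
    """Score one subject's full record.

    The record must contain every raw feature; derived features (plank
    asymmetry) are computed here if absent.  The overall grade is the sum
    of all 21 feature scores, so it ranges from 21 to 105 for the
    default battery.
    """
    if fuzzy is None:
        fuzzy = build_fuzzy_features(config)
    full = derive_features(record, config)
    missing = [n for n in config.feature_names if n not in full]
    if missing:
        raise MissingFeatureError(missing)
    scores = {n: score_feature(full[n], fuzzy[n]) for n in config.feature_names}
    return ScoredRecord.from_scores(scores, config)
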