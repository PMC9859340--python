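"""Expert-threshold configuration for the physiological test battery.

The work-ability battery measures 21 physiological features across three
body systems — cardiovascular (3 features: systolic/diastolic blood
pressure and the Ruffier index), muscular (11: trunk and side-plank
endurance, plank asymmetry, leg strength, sit-down/bend and turn-over
transitions) and nervous (7: static-balance mistake counts, tapping
mobility, poverty and mistake percentages).  Each feature carries an
expert-defined partition of its value range into 3 or 5 threshold levels,
scored 1 (worst) to 5 (best); 3-level features use scores {1, 3, 5}.

The default encoding ships with the package as JSON
(``data/default_thresholds.json``); users may load their own JSON/YAML
file with the same schema via :func:`load_config`.

Interval convention: each level interval is half-open ``[lo, hi)``; the
top level of a feature is closed at the domain maximum, so every value in
the domain belongs to exactly one level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, IntervalError, MissingFeatureError, DomainError

SUBSYSTEMS = ("cardiovascular", "muscular", "nervous")

#: expected feature counts per subsystem in a full battery configuration
SUBSYSTEM_SIZES = {"cardiovascular": 3, "muscular": 11, "nervous": 7}


@dataclass(frozen=True)
class Level:
    """One threshold level: half-open interval ``[lo, hi)`` with its score."""

    lo: float
    hi: float
    score: int

    def contains(self, x: float, *, closed_top: bool = False) -> bool:
        if closed_top:
            return self.lo <= x <= self.hi
        return self.lo <= x < self.hi


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of one physiological feature.

    Parameters
    ----------
    name : str
        Canonical feature identifier (column name in cohort CSVs).
    units : str
        Free-text units of the raw measurement.
    subsystem : str
        One of ``cardiovascular``, ``muscular``, ``nervous``.
    levels : sequence of Level
        Ordered (ascending) partition of ``value_domain`` into scored
        intervals.
    value_domain : (float, float)
        Closed interval of admissible raw values.
    discrete : bool
        True for integer count features (static-balance mistakes); these
        are scored with crisp steps, never with fuzzy transition ramps.
    derived_from : tuple of str, optional
        Source features for derived quantities (plank asymmetry).
    default_halfwidth : float
        Transition-zone halfwidth (feature units) used at every internal
        threshold when no cohort-based spread estimate is available.
    """

    name: str
    units: str
    subsystem: str
    levels: tuple[Level, ...]
    value_domain: tuple[float, float]
    discrete: bool = False
    derived_from: tuple[str, ...] | None = None
    default_halfwidth: float = 0.0

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.value_domain
        if not lo < hi:
            raise ConfigError(f"{self.name}: empty value domain [{lo}, {hi}]")
        if self.subsystem not in SUBSYSTEMS:
            raise ConfigError(f"{self.name}: unknown subsystem {self.subsystem!r}")
        if len(self.levels) < 2:
            raise ConfigError(f"{self.name}: needs at least two levels")
        if self.default_halfwidth < 0:
            raise ConfigError(f"{self.name}: negative default halfwidth")

        prev_hi = lo
        for lv in self.levels:
            if not lv.lo < lv.hi:
                raise IntervalError(
                    f"{self.name}: empty level interval [{lv.lo}, {lv.hi})"
                )
            if not math.isclose(lv.lo, prev_hi, rel_tol=0, abs_tol=1e-12):
                raise IntervalError(
                    f"{self.name}: levels leave a gap or overlap at {lv.lo}"
                )
            prev_hi = lv.hi
        if not math.isclose(prev_hi, hi, rel_tol=0, abs_tol=1e-12):
            raise IntervalError(
                f"{self.name}: levels do not cover the value domain up to {hi}"
            )

        scores = [lv.score for lv in self.levels]
        if not set(scores) <= {1, 2, 3, 4, 5}:
            raise ConfigError(f"{self.name}: scores must lie in 1..5, got {scores}")
        if scores.count(5) != 1:
            raise ConfigError(f"{self.name}: exactly one level must score 5")
        if self.n_levels == 5 and set(scores) != {1, 2, 3, 4, 5}:
            raise ConfigError(f"{self.name}: a 5-level feature must use scores 1..5")
        if self.n_levels == 3 and set(scores) != {1, 3, 5}:
            raise ConfigError(
                f"{self.name}: a 3-level feature must use scores {{1, 3, 5}}"
            )

    # -- accessors ----------------------------------------------------
    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def internal_thresholds(self) -> tuple[float, ...]:
        """Breakpoints between consecutive levels (the expert thresholds)."""
        return tuple(lv.hi for lv in self.levels[:-1])

    def level_index(self, x: float) -> int:
        """Index of the level owning value ``x`` (crisp table lookup)."""
        lo, hi = self.value_domain
        if not lo <= x <= hi:
            raise DomainError(
                f"{self.name}: value {x} outside domain [{lo}, {hi}]"
            )
        for i, lv in enumerate(self.levels):
            if lv.contains(x, closed_top=(i == len(self.levels) - 1)):
                return i
        raise AssertionError("unreachable: levels cover the domain")

    def crisp_score(self, x: float) -> int:
        """Integer table score of value ``x`` (no transition zones)."""
        return self.levels[self.level_index(x)].score

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        lo, hi = self.value_domain
        d = {
            "name": self.name,
            "units": self.units,
            "subsystem": self.subsystem,
            "discrete": self.discrete,
            "value_domain": [lo, hi],
            "default_halfwidth": self.default_halfwidth,
            "levels": [
                {
                    "interval": [
                        None if i == 0 else lv.lo,
                        None if i == len(self.levels) - 1 else lv.hi,
                    ],
                    "score": lv.score,
                }
                for i, lv in enumerate(self.levels)
            ],
        }
        if self.derived_from:
            d["derived_from"] = list(self.derived_from)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        try:
            name = d["name"]
            lo, hi = d["value_domain"]
            raw_levels = d["levels"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed feature entry: {d!r}") from exc
        levels = []
        for entry in raw_levels:
            a, b = entry["interval"]
            levels.append(
                Level(
                    lo=float(lo) if a is None else float(a),
                    hi=float(hi) if b is None else float(b),
                    score=int(entry["score"]),
                )
            )
        levels.sort(key=lambda lv: lv.lo)
        derived = d.get("derived_from")
        return cls(
            name=name,
            units=d.get("units", ""),
            subsystem=d["subsystem"],
            levels=tuple(levels),
            value_domain=(float(lo), float(hi)),
            discrete=bool(d.get("discrete", False)),
            derived_from=tuple(derived) if derived else None,
            default_halfwidth=float(d.get("default_halfwidth", 0.0)),
        )


@dataclass(frozen=True)
class ExpertConfig:
    """The full expert knowledge base: 21 feature specs in three subsystems."""

    features: tuple[FeatureSpec, ...]
    strict: bool = field(default=True, compare=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate feature name(s): {sorted(dupes)}")
        raw = {f.name for f in self.features if f.derived_from is None}
        for f in self.features:
            for src in f.derived_from or ():
                if src not in raw:
                    raise ConfigError(
                        f"{f.name}: derived_from source {src!r} is not a raw feature"
                    )
        if self.strict:
            for f in self.features:
                if f.n_levels not in (3, 5):
                    raise ConfigError(
                        f"{f.name}: battery features must have 3 or 5 levels"
                    )
            counts = {s: len(self.subsystem_features(s)) for s in SUBSYSTEMS}
            if counts != SUBSYSTEM_SIZES:
                raise ConfigError(
                    f"subsystem sizes must be {SUBSYSTEM_SIZES}, got {counts}"
                )

    # -- accessors ----------------------------------------------------
    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def raw_feature_names(self) -> list[str]:
        """Names of directly measured features (derived ones excluded)."""
        return [f.name for f in self.features if f.derived_from is None]

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subsystem_features(self, subsystem: str) -> list[FeatureSpec]:
        return [f for f in self.features if f.subsystem == subsystem]

    @property
    def subsystem_index(self) -> dict[str, list[str]]:
        return {
            s: [f.name for f in self.subsystem_features(s)] for s in SUBSYSTEMS
        }

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {"features": [f.to_dict() for f in self.features]}

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix.lower() in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_dict(cls, d: Mapping, *, strict: bool = True) -> "ExpertConfig":
        if "features" not in d:
            raise ConfigError("configuration must contain a 'features' list")
        return cls(
            features=tuple(FeatureSpec.from_dict(e) for e in d["features"]),
            strict=strict,
        )


def load_config(path: str | Path, *, strict: bool = True) -> ExpertConfig:
    """Load and validate an expert-threshold configuration (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return ExpertConfig.from_dict(payload, strict=strict)


def default_config() -> ExpertConfig:
    """The built-in expert encoding of the 21-feature battery thresholds."""
    text = (
        resources.files("workability.data")
        .joinpath("default_thresholds.json")
        .read_text()
    )
    return ExpertConfig.from_dict(json.loads(text))


def derive_features(record: Mapping[str, float], config: ExpertConfig) -> dict:
    """Add derived features (plank asymmetry) to a raw record.

    Plank asymmetry is the absolute difference of the left and right
    side-plank hold times, in seconds.  Raw features pass through
    unchanged; a derived value already present in the record is kept.
    """
    out = dict(record)
    for f in config.features:
        if not f.derived_from or f.name in out:
            continue
        missing = [s for s in f.derived_from if s not in out]
        if missing:
            raise MissingFeatureError(missing)
        a, b = (out[s] for s in f.derived_from)
        out[f.name] = abs(a - b)
    return out


def derive_features_frame(frame, config: ExpertConfig):
    """Vectorized :func:`derive_features` over a pandas DataFrame."""
    out = frame.copy()
    for f in config.features:
        if not f.derived_from or f.name in out.columns:
            continue
        missing = [s for s in f.derived_from if s not in out.columns]
        if missing:
            raise MissingFeatureError(missing)
        a, b = f.derived_from
        out[f.name] = (out[a] - out[b]).abs()
    return out
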