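"""Synthetic cohort generator with a latent health factor.

No public dataset accompanies the work-ability battery, so the package
ships a simulator whose per-feature marginals reproduce the reference
cohort statistics (means ± SDs of the 98-subject field study, e.g.
systolic blood pressure 124.40 ± 12.99 mmHg, Ruffier index 8.88 ± 4.79,
back endurance 251.89 ± 64.72 s).  A single standard-normal latent
health factor h couples the features:

    value = mean + SD * (orientation * loading * h
                         + sqrt(1 - loading^2) * noise)

where ``orientation`` is the feature's healthy direction (+1 when
larger raw values score better, -1 when smaller do; 0 for the two
blood pressures, whose optimum is an interior band a linear factor
cannot express).  Left/right paired tests share half of their noise
variance so lateral asymmetry stays realistic.  Values are truncated
to the feature's admissible domain by resampling the noise (avoiding
boundary atoms), and discrete mistake counts are rounded to
nonnegative integers.  With loading 0 all features are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ExpertConfig, default_config
from .errors import ConfigError

#: reference cohort marginals: feature -> (mean, SD)
FEATURE_STATS: dict[str, tuple[float, float]] = {
    "BPhigh": (124.40, 12.99),
    "BPlow": (77.56, 8.33),
    "RFTest": (8.88, 4.79),
    "Back": (251.89, 64.72),
    "Abdomen": (191.96, 92.34),
    "LeftPlank": (63.06, 33.02),
    "RightPlank": (65.04, 32.87),
    "LeftLeg": (19.60, 4.03),
    "RightLeg": (20.45, 4.57),
    "SitDown": (6.09, 0.92),
    "Bend": (6.02, 0.77),
    "TurnToRight": (3.57, 1.17),
    "TurnToLeft": (3.51, 1.03),
    "LeftOpened": (0.95, 0.58),
    "RightOpened": (0.89, 0.43),
    "LeftClosed": (2.99, 2.58),
    "RightClosed": (3.08, 2.59),
    "Poverty": (6.52, 2.43),
    "Mistakes": (3.57, 1.28),
    "Mobility": (6.37, 0.74),
}

#: healthy direction of each raw feature (+1 higher is better, -1 lower,
#: 0 band-shaped optimum).  Poverty follows its threshold table (>25 best).
ORIENTATION: dict[str, int] = {
    "BPhigh": 0,
    "BPlow": 0,
    "RFTest": -1,
    "Back": 1,
    "Abdomen": 1,
    "LeftPlank": 1,
    "RightPlank": 1,
    "LeftLeg": 1,
    "RightLeg": 1,
    "SitDown": -1,
    "Bend": -1,
    "TurnToRight": -1,
    "TurnToLeft": -1,
    "LeftOpened": -1,
    "RightOpened": -1,
    "LeftClosed": -1,
    "RightClosed": -1,
    "Poverty": 1,
    "Mistakes": -1,
    "Mobility": 1,
}

#: left/right test pairs sharing a symmetric noise component
PAIRS: tuple[tuple[str, str], ...] = (
    ("LeftPlank", "RightPlank"),
    ("LeftLeg", "RightLeg"),
    ("TurnToRight", "TurnToLeft"),
    ("LeftOpened", "RightOpened"),
    ("LeftClosed", "RightClosed"),
)

#: reference cohort composition (metadata only; no effect on features)
N_FEMALE, N_MALE = 57, 41
AGE_MEAN, AGE_SD = 38.02, 11.77

_MAX_RESAMPLE = 200


@dataclass(frozen=True)
class SynthConfig:
    """Simulation parameters (defaults emulate the reference cohort)."""

    n: int = 98
    loading: float = 0.6
    seed: int = 0
    pair_share: float = 0.5
    means: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    orientations: Mapping[str, int] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    include_metadata: bool = True

    def __post_init__(self):
        if self.n < 4:
            raise ConfigError("cohort needs at least 4 subjects")
        if not 0.0 <= self.loading <= 1.0:
            raise ConfigError("latent loading must lie in [0, 1]")
        if not 0.0 <= self.pair_share <= 1.0:
            raise ConfigError("pair_share must lie in [0, 1]")
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ConfigError(f"{name}: SD must be positive")
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ConfigError(f"{name}: invalid bounds [{lo}, {hi}]")

    def stat(self, name: str) -> tuple[float, float]:
        mean, sd = FEATURE_STATS[name]
        return self.means.get(name, mean), self.sds.get(name, sd)

    def orientation(self, name: str) -> int:
        return self.orientations.get(name, ORIENTATION[name])


@dataclass
class Cohort:
    """A simulated cohort: feature table plus the true latent health."""

    frame: pd.DataFrame
    latent: np.ndarray

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path, **kwargs) -> None:
        kwargs.setdefault("index_label", "id")
        self.frame.to_csv(path, **kwargs)


def _pair_partner(name: str) -> str | None:
    for a, b in PAIRS:
        if name == a:
            return b
        if name == b:
            return a
    return None


def generate_cohort(
    cfg: SynthConfig = SynthConfig(), config: ExpertConfig | None = None
) -> Cohort:
    """Draw a synthetic cohort of raw measurements.

    Truncation bounds default to each feature's admissible value domain
    from the expert configuration; out-of-bounds draws are resampled
    (idiosyncratic noise only, keeping the latent factor fixed).
    Discrete counts are checked against their bounds after rounding.
    """
    config = config if config is not None else default_config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    latent = rng.standard_normal(n)
    loading = cfg.loading
    resid = np.sqrt(1.0 - loading**2)

    pair_noise = {pair: rng.standard_normal(n) for pair in PAIRS}

    columns: dict[str, np.ndarray] = {}
    for spec in config:
        if spec.derived_from:
            continue  # derived downstream
        name = spec.name
        mean, sd = cfg.stat(name)
        orient = cfg.orientation(name)
        lo, hi = cfg.bounds.get(name, spec.value_domain)
        base = orient * loading * latent

        partner = _pair_partner(name)
        if partner is not None:
            pair_key = next(p for p in PAIRS if name in p)
            shared = np.sqrt(cfg.pair_share) * pair_noise[pair_key]
            own_scale = np.sqrt(1.0 - cfg.pair_share)
        else:
            shared = 0.0
            own_scale = 1.0

        noise = shared + own_scale * rng.standard_normal(n)
        values = mean + sd * (base + resid * noise)

        # truncate by resampling the idiosyncratic noise
        eff_lo, eff_hi = (lo - 0.5, hi + 0.5) if spec.discrete else (lo, hi)
        out = (values < eff_lo) | (values > eff_hi)
        tries = 0
        while np.any(out) and tries < _MAX_RESAMPLE:
            redraw = shared + own_scale * rng.standard_normal(n)
            values = np.where(
                out, mean + sd * (base + resid * redraw), values
            )
            out = (values < eff_lo) | (values > eff_hi)
            tries += 1
        if np.any(out):  # pathological config: give up and clip
            values = np.clip(values, eff_lo, eff_hi)

        if spec.discrete:
            values = np.clip(np.rint(values), lo, hi).astype(int)
        columns[name] = values

    frame = pd.DataFrame(columns, index=_subject_ids(n))
    if cfg.include_metadata:
        p_female = N_FEMALE / (N_FEMALE + N_MALE)
        frame.insert(0, "sex", np.where(rng.random(n) < p_female, "F", "M"))
        age = AGE_MEAN + AGE_SD * rng.standard_normal(n)
        frame.insert(1, "age", np.clip(age, 18.0, 80.0).round(1))
    return Cohort(frame=frame, latent=latent)


def _subject_ids(n: int) -> pd.Index:
    width = max(3, len(str(n)))
    return pd.Index([f"S{i + 1:0{width}d}" for i in range(n)], name="id")


def generate_labeled_benchmark(
    cfg: SynthConfig = SynthConfig(), config: ExpertConfig | None = None
) -> tuple[Cohort, np.ndarray]:
    """Cohort plus each subject's latent-health tercile (0 worst, 2 best).

    The terciles are the ground truth for parameter-recovery checks:
    with a substantial loading, subjects in the lowest latent tercile
    should be enriched for the C1/C2 classes after scoring + labeling.
    """
    if cfg.loading <= 0:
        raise ConfigError("benchmark generation needs a positive latent loading")
    cohort = generate_cohort(cfg, config)
    cuts = np.quantile(cohort.latent, [1 / 3, 2 / 3])
    terciles = np.digitize(cohort.latent, cuts)
    return cohort, terciles
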