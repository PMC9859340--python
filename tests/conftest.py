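import pytest

from workability import FuzzyScorer, default_config
from workability.fuzzy import build_fuzzy_features
from workability.labeling import label_cohort
from workability.simulate import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fuzzy_default(config):
    """Fuzzy features built with the config's default halfwidths."""
    return build_fuzzy_features(config)


@pytest.fixture(scope="session")
def cohort98():
    """Default-sized synthetic cohort (98 subjects, moderate loading)."""
    return generate_cohort(SynthConfig(n=98, seed=11))


@pytest.fixture(scope="session")
def scored98(cohort98, config):
    scorer = FuzzyScorer(config=config).fit(cohort98.frame)
    return scorer.score_table(cohort98.frame)


@pytest.fixture(scope="session")
def labeled98(scored98):
    return label_cohort(scored98, per_system=True)


def plateau_value(spec, score):
    """Midpoint of the level carrying ``score`` (deep inside its plateau)."""
    for lv in spec.levels:
        if lv.score == score:
            lo = max(lv.lo, spec.value_domain[0])
            hi = min(lv.hi, spec.value_domain[1])
            return (lo + hi) / 2.0
    raise ValueError(f"{spec.name} has no level scored {score}")


@pytest.fixture(scope="session")
def perfect_record(config):
    """A raw record whose every feature sits in its score-5 plateau."""
    rec = {}
    for spec in config:
        if spec.derived_from:
            continue
        rec[spec.name] = plateau_value(spec, 5)
    # plank asymmetry must itself land in its score-5 level (< 50 s)
    rec["RightPlank"] = rec["LeftPlank"]
    return rec
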