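import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from workability import (
    build_fuzzy_feature,
    build_fuzzy_features,
    left_membership,
    right_membership,
    score_feature,
    score_record,
    transition_zone,
    trapezium_membership,
)
from workability.config import FeatureSpec, Level
from workability.errors import (
    ConfigError,
    DomainError,
    MissingFeatureError,
    ParameterError,
)
from workability.fuzzy import estimate_threshold_sds

from conftest import plateau_value


def two_level_spec(threshold=25.0, lo=0.0, hi=100.0):
    """A minimal feature: best below the threshold, worst above."""
    return FeatureSpec(
        name="demo", units="", subsystem="muscular",
        levels=(Level(lo, threshold, 5), Level(threshold, hi, 1)),
        value_domain=(lo, hi),
    )


class TestMembershipPrimitives:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (-1.0, 0.0), (0.0, 0.0), (0.5, 0.5), (1.0, 1.0), (1.5, 1.0),
            (2.0, 1.0), (2.75, 0.25), (3.0, 0.0), (5.0, 0.0),
        ],
    )
    def test_trapezium_piecewise(self, x, expected):
        assert trapezium_membership(x, 0, 1, 2, 3) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x,expected",
        [(-5.0, 1.0), (2.0, 1.0), (3.0, 0.5), (4.0, 0.0), (14.0, 0.0)],
    )
    def test_left_curve(self, x, expected):
        assert left_membership(x, 2, 4) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x,expected",
        [(-5.0, 0.0), (2.0, 0.0), (3.0, 0.5), (4.0, 1.0), (14.0, 1.0)],
    )
    def test_right_curve(self, x, expected):
        assert right_membership(x, 2, 4) == pytest.approx(expected)

    def test_side_curves_complementary(self):
        xs = np.linspace(-10, 20, 501)
        total = left_membership(xs, 2, 8) + right_membership(xs, 2, 8)
        assert np.allclose(total, 1.0)

    def test_zero_width_ramps_are_steps(self):
        assert left_membership(4.999, 5, 5) == 1.0
        assert left_membership(5.0, 5, 5) == 0.0
        assert right_membership(5.0, 5, 5) == 1.0
        assert trapezium_membership(5.0, 5, 5, 7, 7) == 1.0
        assert trapezium_membership(7.0, 5, 5, 7, 7) == 0.0

    @pytest.mark.parametrize(
        "fn,knots",
        [
            (trapezium_membership, (3, 2, 4, 5)),
            (trapezium_membership, (0, 1, 5, 4)),
            (left_membership, (4, 2)),
            (right_membership, (4, 2)),
        ],
    )
    def test_unordered_knots_rejected(self, fn, knots):
        with pytest.raises(ParameterError):
            fn(1.0, *knots)

    @given(
        knots=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=4
        ).map(sorted),
        x=st.floats(-200, 200, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_membership_always_in_unit_interval(self, knots, x):
        mu = trapezium_membership(x, *knots)
        assert 0.0 <= mu <= 1.0


class TestTransitionZones:
    def test_worked_example_threshold_25_sd_8(self):
        """SD 8 around threshold 25 puts the ramp between 21 and 29."""
        assert transition_zone(25, 8) == (21.0, 29.0)
        ff = build_fuzzy_feature(two_level_spec(25), threshold_sds={25: 8.0})
        lower = ff.curves[0]
        assert lower.shape == "left" and lower.knots == (21.0, 29.0)
        upper = ff.curves[1]
        assert upper.shape == "right" and upper.knots == (21.0, 29.0)

    def test_zero_sd_gives_crisp_steps(self, config):
        ff = build_fuzzy_feature(config["RFTest"], threshold_sds=0.0)
        xs = np.linspace(*config["RFTest"].value_domain, 1001)
        mu = ff.memberships(xs)
        assert set(np.unique(mu)) <= {0.0, 1.0}

    def test_rftest_value_between_zones_is_plateau(self, config):
        """RFTest with per-threshold SD 2: value 8 sits wholly in the 6-10 level."""
        sds = {0.0: 2.0, 3.0: 2.0, 6.0: 2.0, 10.0: 2.0}
        ff = build_fuzzy_feature(config["RFTest"], threshold_sds=sds)
        assert len(ff.curves) == 5
        mu = ff.memberships(8.0).ravel()
        scores = [c.score for c in ff.curves]
        assert mu[scores.index(2)] == 1.0
        assert mu.sum() == pytest.approx(1.0)
        assert score_feature(8.0, ff) == pytest.approx(2.0)

    def test_zones_clipped_to_half_gap(self, config):
        # RFTest gaps are 3, 3, 4: an SD of 100 must clip to half the gap
        ff = build_fuzzy_feature(config["RFTest"], threshold_sds=100.0)
        assert max(ff.halfwidths) <= 2.0

    def test_zone_beyond_domain_rejected(self):
        spec = two_level_spec(threshold=5.0, lo=0.0, hi=100.0)
        with pytest.raises(ConfigError, match="domain"):
            build_fuzzy_feature(spec, threshold_sds={5.0: 20.0})

    def test_discrete_features_ignore_sds(self, config):
        ff = build_fuzzy_feature(config["LeftOpened"], threshold_sds=10.0)
        assert ff.halfwidths == (0.0,) * 4

    def test_estimate_sds_uses_upper_bin(self):
        spec = two_level_spec(25)
        values = np.concatenate([np.full(10, 10.0), [30.0, 40.0, 50.0]])
        sds = estimate_threshold_sds(values, spec)
        assert sds[25.0] == pytest.approx(np.std([30, 40, 50], ddof=1))

    def test_sparse_bins_fall_back_to_default(self):
        spec = two_level_spec(25)
        assert estimate_threshold_sds([10.0, 12.0, 99.0], spec) == {}


class TestScoring:
    def test_low_plateau_scores_one(self, config, fuzzy_default):
        assert score_feature(12.0, fuzzy_default["RFTest"]) == pytest.approx(1.0)

    def test_high_plateau_scores_five(self, config, fuzzy_default):
        assert score_feature(-1.0, fuzzy_default["RFTest"]) == pytest.approx(5.0)

    def test_threshold_midpoint_averages_neighbours(self, config):
        ff = build_fuzzy_feature(config["RFTest"], threshold_sds=2.0)
        # at threshold 6, levels scored 3 and 2 each hold membership 0.5
        assert score_feature(6.0, ff) == pytest.approx(2.5)

    def test_out_of_domain_rejected(self, fuzzy_default):
        with pytest.raises(DomainError):
            score_feature(35.0, fuzzy_default["RFTest"])

    def test_partition_of_unity_all_features(self, config, cohort98):
        """Level memberships sum to 1 on dense grids, for default and
        cohort-estimated transition zones alike."""
        from workability import FuzzyScorer

        for fuzzy in (
            build_fuzzy_features(config),
            FuzzyScorer(config=config).fit(cohort98.frame).fuzzy_features_,
        ):
            for name, ff in fuzzy.items():
                xs = np.linspace(*ff.spec.value_domain, 1000)
                total = ff.memberships(xs).sum(axis=0)
                assert np.allclose(total, 1.0, atol=1e-9), name

    def test_plateau_fidelity(self, config, fuzzy_default):
        """Away from every transition zone the integer table score is exact."""
        rng = np.random.default_rng(0)
        for name, ff in fuzzy_default.items():
            spec = ff.spec
            lo, hi = spec.value_domain
            thresholds = spec.internal_thresholds
            h = max(ff.halfwidths) if ff.halfwidths else 0.0
            xs = rng.uniform(lo, hi, 300)
            far = np.array(
                [all(abs(x - t) > h + 1e-9 for t in thresholds) for x in xs]
            )
            for x in xs[far]:
                assert score_feature(x, ff) == spec.crisp_score(x), name

    def test_monotone_scoring(self, config, fuzzy_default):
        """Score is monotone in x wherever the level scores are."""
        for name, direction in [("Back", 1), ("RFTest", -1), ("Mobility", 1),
                                ("SitDown", -1), ("PlankAs", -1)]:
            ff = fuzzy_default[name]
            xs = np.linspace(*ff.spec.value_domain, 1000)
            diffs = np.diff(score_feature(xs, ff)) * direction
            assert np.all(diffs >= -1e-12), name

    def test_crisp_limit_recovers_table_lookup(self, config):
        for name in ("RFTest", "Back", "BPhigh", "Poverty"):
            spec = config[name]
            ff = build_fuzzy_feature(spec, halfwidths=0.0)
            xs = np.linspace(*spec.value_domain, 777)
            expected = np.array([spec.crisp_score(x) for x in xs])
            assert np.allclose(score_feature(xs, ff), expected), name


class TestScoreRecord:
    def test_perfect_record_totals_105(self, config, perfect_record):
        scored = score_record(perfect_record, config)
        assert scored.total == pytest.approx(105.0)
        assert sum(scored.subsystem_sums.values()) == pytest.approx(105.0)
        assert scored.subsystem_sums["cardiovascular"] == pytest.approx(15.0)

    def test_worst_record_totals_21(self, config):
        rec = {
            spec.name: plateau_value(spec, 1)
            for spec in config
            if not spec.derived_from
        }
        rec["PlankAs"] = 100.0  # worst asymmetry band, supplied directly
        scored = score_record(rec, config)
        assert scored.total == pytest.approx(21.0)

    def test_single_low_feature_drops_four_points(self, config, perfect_record):
        rec = dict(perfect_record, RFTest=12.0)
        assert score_record(rec, config).total == pytest.approx(101.0)

    def test_missing_features_listed(self, config, perfect_record):
        rec = dict(perfect_record)
        del rec["Back"], rec["Mobility"]
        with pytest.raises(MissingFeatureError) as err:
            score_record(rec, config)
        assert {"Back", "Mobility"} <= set(err.value.missing)
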