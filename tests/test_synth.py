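import numpy as np
import pandas as pd
import pytest
from scipy import stats

from workability import FuzzyScorer, generate_cohort, generate_labeled_benchmark
from workability.errors import ConfigError
from workability.labeling import label_cohort
from workability.simulate import (
    FEATURE_STATS,
    ORIENTATION,
    PAIRS,
    SynthConfig,
)


class TestGenerateCohort:
    def test_default_cohort_size_and_columns(self, cohort98, config):
        assert cohort98.n == 98
        for name in config.raw_feature_names:
            assert name in cohort98.frame.columns
        assert "PlankAs" not in cohort98.frame.columns  # derived downstream
        assert {"sex", "age"} <= set(cohort98.frame.columns)
        assert cohort98.latent.shape == (98,)

    def test_same_seed_identical(self):
        a = generate_cohort(SynthConfig(n=50, seed=4))
        b = generate_cohort(SynthConfig(n=50, seed=4))
        pd.testing.assert_frame_equal(a.frame, b.frame)
        np.testing.assert_array_equal(a.latent, b.latent)

    def test_different_seeds_differ(self):
        a = generate_cohort(SynthConfig(n=50, seed=4))
        b = generate_cohort(SynthConfig(n=50, seed=5))
        assert not a.frame.equals(b.frame)

    def test_no_missing_cells_and_bounds(self, config):
        cohort = generate_cohort(SynthConfig(n=500, seed=8, loading=0.9))
        frame = cohort.frame[config.raw_feature_names]
        assert not frame.isna().any().any()
        for spec in config:
            if spec.derived_from:
                continue
            lo, hi = spec.value_domain
            col = frame[spec.name]
            assert col.between(lo, hi).all(), spec.name
            if spec.discrete:
                assert (col == col.astype(int)).all(), spec.name

    def test_marginals_match_at_zero_loading(self):
        """Independent features: large-sample mean/SD track the targets."""
        cohort = generate_cohort(SynthConfig(n=5000, seed=1, loading=0.0))
        bp = cohort.frame["BPhigh"]
        assert abs(bp.mean() - 124.40) < 1.0
        assert abs(bp.std() - 12.99) < 1.0
        for name in ("RFTest", "Back", "SitDown", "Mobility"):
            mean, sd = FEATURE_STATS[name]
            col = cohort.frame[name]
            assert abs(col.mean() - mean) < 0.2 * sd, name
            assert abs(col.std() - sd) < 0.2 * sd, name

    def test_truncation_moves_little_mass(self, config):
        """The nominal Gaussian rarely leaves the admissible domain.

        The closed-eyes balance counts are the exception: their printed
        mean/SD (about 3.0 +/- 2.6 mistakes) place roughly 9% of the
        Gaussian below zero, so only a 10% ceiling is attainable there.
        """
        rng = np.random.default_rng(0)
        for spec in config:
            if spec.derived_from:
                continue
            mean, sd = FEATURE_STATS[spec.name]
            lo, hi = spec.value_domain
            if spec.discrete:
                lo, hi = lo - 0.5, hi + 0.5
            draws = rng.normal(mean, sd, size=5000)
            moved = np.mean((draws < lo) | (draws > hi))
            ceiling = 0.10 if spec.name in ("LeftClosed", "RightClosed") else 0.05
            assert moved <= ceiling, f"{spec.name}: {moved:.3f}"

    def test_orientation_latent_improves_scores(self, config):
        """At loading 0.9 a healthier latent means better scores, feature-wise."""
        cohort = generate_cohort(SynthConfig(n=400, seed=6, loading=0.9))
        for spec in config:
            if spec.derived_from or ORIENTATION[spec.name] == 0:
                continue
            scores = [spec.crisp_score(v) for v in cohort.frame[spec.name]]
            rho = stats.spearmanr(cohort.latent, scores).statistic
            assert rho > 0.2, f"{spec.name}: rho={rho:.2f}"

    def test_paired_features_correlate(self):
        cohort = generate_cohort(SynthConfig(n=2000, seed=2, loading=0.0))
        for a, b in PAIRS:
            r = np.corrcoef(cohort.frame[a], cohort.frame[b])[0, 1]
            assert r > 0.25, (a, b)

    def test_minimal_cohort_passes_pipeline(self, config):
        cohort = generate_cohort(SynthConfig(n=4, seed=0))
        scorer = FuzzyScorer(config=config).fit(cohort.frame)
        table = scorer.score_table(cohort.frame)
        labels = label_cohort(table, per_system=True)
        assert len(labels) == 4

    def test_csv_round_trip(self, tmp_path):
        cohort = generate_cohort(SynthConfig(n=10, seed=3))
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = pd.read_csv(path, index_col="id")
        assert list(back.index) == list(cohort.frame.index)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 3},
            {"loading": 1.5},
            {"sds": {"BPhigh": -1.0}},
            {"bounds": {"BPhigh": (100, 90)}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SynthConfig(**kwargs)


class TestLabeledBenchmark:
    def test_terciles_balanced(self):
        cohort, terciles = generate_labeled_benchmark(
            SynthConfig(n=300, seed=9, loading=0.9)
        )
        counts = np.bincount(terciles, minlength=3)
        assert counts.min() >= 90

    def test_low_latent_tercile_enriched_for_poor_classes(self, config):
        cohort, terciles = generate_labeled_benchmark(
            SynthConfig(n=300, seed=10, loading=0.9)
        )
        scorer = FuzzyScorer(config=config).fit(cohort.frame)
        labels = label_cohort(scorer.score_table(cohort.frame))
        low = labels.loc[np.asarray(terciles) == 0, "label_overall"]
        assert (low <= 1).mean() >= 0.6

    def test_zero_loading_breaks_association(self, config):
        """Without a latent signal the label is independent of the tercile."""
        ok = 0
        for seed in range(10):
            cohort = generate_cohort(SynthConfig(n=150, seed=seed, loading=0.0))
            cuts = np.quantile(cohort.latent, [1 / 3, 2 / 3])
            terciles = np.digitize(cohort.latent, cuts)
            scorer = FuzzyScorer(config=config).fit(cohort.frame)
            labels = label_cohort(scorer.score_table(cohort.frame))
            table = pd.crosstab(terciles, labels["label_overall"])
            p = stats.chi2_contingency(table).pvalue
            ok += p > 0.01
        assert ok >= 9

    def test_requires_positive_loading(self):
        with pytest.raises(ConfigError):
            generate_labeled_benchmark(SynthConfig(loading=0.0))
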