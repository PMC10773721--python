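import numpy as np
import pytest

from injurycast import evaluation as ev
from injurycast import models, resampling, windowing


class TestConfusionAndMetrics:
    def test_sensitivity_from_counts(self):
        m = ev.metrics(ev.ConfusionCounts(tp=3, fp=0, tn=0, fn=1))
        assert m.sensitivity == 0.75

    def test_reference_gmean_rounds_to_printed_value(self):
        got = float(np.sqrt(0.998 * 0.947))
        assert round(got, 3) == 0.972

    def test_confusion_counts_partition_the_sample(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(size=50)
        cc = ev.confusion(y, p, threshold=0.4)
        assert cc.total == 50

    def test_perfect_and_reversed_ranking_auc(self):
        y = np.array([0, 0, 1, 1])
        assert ev.metrics(ev.confusion(y, np.array([0.1, 0.2, 0.8, 0.9])),
                          y, np.array([0.1, 0.2, 0.8, 0.9])).auc == 1.0
        assert ev.metrics(ev.confusion(y, np.array([0.9, 0.8, 0.2, 0.1])),
                          y, np.array([0.9, 0.8, 0.2, 0.1])).auc == 0.0

    def test_auc_equals_rank_probability(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        p = rng.uniform(size=80)
        m = ev.metrics(ev.confusion(y, p), y, p)
        pos, neg = p[y == 1], p[y == 0]
        pairs = (pos[:, None] > neg[None, :]).mean() + 0.5 * (pos[:, None] == neg[None, :]).mean()
        np.testing.assert_allclose(m.auc, pairs, atol=1e-12)

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        p = rng.uniform(size=100)
        base = ev.metrics(ev.confusion(y, p), y, p).auc
        for f in (np.exp, lambda v: 3 * v + 1, lambda v: 1 / (1 + np.exp(-v)), np.cbrt):
            assert ev.metrics(ev.confusion(y, p), y, f(p)).auc == base

    def test_gmean_identity_on_random_metric_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            p = rng.uniform(size=60)
            m = ev.metrics(ev.confusion(y, p), y, p)
            np.testing.assert_allclose(m.gmean,
                                       np.sqrt(m.sensitivity * m.specificity), atol=1e-15)

    def test_single_class_auc_rejected(self):
        y = np.ones(5, dtype=int)
        with pytest.raises(ValueError, match="one class"):
            ev.metrics(ev.confusion(y, np.full(5, 0.7)), y, np.full(5, 0.7))


class TestRelativeDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (0.891, 0.719, 23.9),   # AUC vs baseline
        (0.830, 0.651, 27.5),   # Gmean
        (0.816, 0.584, 39.7),   # sensitivity
        (0.845, 0.727, 16.2),   # specificity
    ])
    def test_published_improvements_reproduce(self, a, b, expected):
        assert round(ev.relative_difference(a, b), 1) == expected

    @pytest.mark.parametrize("a,b,expected", [
        (0.868, 0.947, 8.34),
        (0.830, 0.842, 1.43),
        (0.892, 0.947, 5.81),
    ])
    def test_published_deficits_reproduce(self, a, b, expected):
        assert round(abs(ev.relative_difference(a, b)), 2) == expected

    def test_identical_values_give_zero(self):
        assert ev.relative_difference(0.5, 0.5) == 0.0

    def test_signed_mean_difference_convention(self):
        assert round(ev.mean_difference(0.891, 0.719), 3) == -0.172

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ev.relative_difference(0.5, 0.0)


class TestLowDiscrepancySubset:
    def test_size_sorted_distinct(self):
        idx = ev.low_discrepancy_subset(100, 37, offset=0.3)
        assert len(idx) == 37 == len(set(idx.tolist()))
        assert (np.diff(idx) > 0).all()

    def test_deterministic(self):
        a = ev.low_discrepancy_subset(50, 20, offset=0.7)
        b = ev.low_discrepancy_subset(50, 20, offset=0.7)
        np.testing.assert_array_equal(a, b)

    def test_golden_sequence_spreads_evenly(self):
        # selections in each half of the index range should be near-balanced
        idx = ev.low_discrepancy_subset(1000, 500, offset=0.11)
        assert abs((idx < 500).sum() - 250) <= 10

    def test_sobol_variant(self):
        idx = ev.low_discrepancy_subset(64, 16, offset=0.5, sequence="sobol")
        assert len(idx) == 16


def _micro_config(seed=0, repeats=1):
    return ev.HoldoutConfig(
        method="gasf",
        plan=resampling.ResamplingPlan(n_injured_target=20, ratio=0.5, smote_k=3,
                                       per_athlete_k=3),
        autoencoder=models.AutoencoderSpec(conv_channels=(4, 8), epochs=2),
        classifier=models.ClassifierSpec(hidden_units=(8, 8), epochs=2),
        repeats=repeats, seed=seed,
    )


@pytest.fixture(scope="module")
def split_windows(small_windows):
    X, y, aids, days = small_windows
    wins = [windowing.WindowSample(a, d, m, l)
            for a, d, m, l in zip(aids, days, X, y)]
    athletes = sorted({w.athlete_id for w in wins})
    test_set = set(athletes[:2])
    return ([w for w in wins if w.athlete_id not in test_set],
            [w for w in wins if w.athlete_id in test_set])


class TestHoldoutProtocol:
    def test_repeats_yield_one_metric_set_per_surface(self, split_windows):
        train, test = split_windows
        report = ev.holdout_protocol(train, test, _micro_config(repeats=2))
        assert len(report.validation) == 2 and len(report.test) == 2
        assert "test_auc_mean" in report.summary

    def test_identical_config_reproduces_report(self, split_windows):
        train, test = split_windows
        r1 = ev.holdout_protocol(train, test, _micro_config(seed=5))
        r2 = ev.holdout_protocol(train, test, _micro_config(seed=5))
        assert r1.summary == r2.summary

    def test_athlete_overlap_rejected(self, split_windows):
        train, test = split_windows
        with pytest.raises(ValueError, match="both splits"):
            ev.holdout_protocol(train, train[:5], _micro_config())


class TestWelchAnova:
    def test_identical_groups_are_not_significant(self):
        g = [np.array([1.0, 2.0, 3.0, 4.0])] * 3
        res = ev.welch_anova(g)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        for cmp in ev.games_howell(g):
            assert cmp.md == 0.0

    def test_two_group_anova_equals_welch_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 14)
        res = ev.welch_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        np.testing.assert_allclose(res.p, t.pvalue, atol=1e-12)

    def test_matches_reference_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 12), rng.normal(0.8, 2, 9), rng.normal(-0.5, 0.5, 15)]
        df = pd.DataFrame({"y": np.concatenate(groups),
                           "g": np.repeat(["a", "b", "c"], [12, 9, 15])})
        ours = ev.welch_anova(groups)
        ref = pg.welch_anova(dv="y", between="g", data=df)
        np.testing.assert_allclose(ours.f, ref["F"].iloc[0], atol=1e-6)
        np.testing.assert_allclose(ours.df2, ref["ddof2"].iloc[0], atol=1e-6)
        np.testing.assert_allclose(ours.p, ref["p_unc"].iloc[0], atol=1e-6)

        ref2 = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        for cmp, (_, row) in zip(ev.games_howell(groups), ref2.iterrows()):
            np.testing.assert_allclose(cmp.t, row["T"], atol=1e-6)
            np.testing.assert_allclose(cmp.df, row["df"], atol=1e-6)
            np.testing.assert_allclose(cmp.p, row["pval"], atol=1e-6)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ev.welch_anova([np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])])
        with pytest.raises(ValueError, match="fewer than 2"):
            ev.welch_anova([np.array([1.0]), np.array([1.0, 2.0])])
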