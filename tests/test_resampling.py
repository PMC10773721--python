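import numpy as np
import pytest

from injurycast import resampling as R


def _toy(n_inj=6, n_uninj=30, n_athletes=3, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n_inj + n_uninj, dim))
    y = np.array([1] * n_inj + [0] * n_uninj)
    aids = np.array([f"a{i % n_athletes}" for i in range(len(y))])
    return X, y, aids


class TestBalancedPerAthleteSample:
    def test_two_athletes_k3_yield_twelve_samples(self):
        X, y, aids = _toy(n_inj=4, n_uninj=10, n_athletes=2)
        out = R.balanced_per_athlete_sample(X, y, aids, k=3, seed=1)
        assert len(out.y) == 12
        assert (out.y == 1).sum() == 6 == (out.y == 0).sum()

    def test_single_injured_sample_repeats_with_replacement(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        aids = np.array(["a"] * 8)
        out = R.balanced_per_athlete_sample(X, y, aids, k=3, seed=0)
        inj_rows = out.X[out.y == 1]
        assert len(inj_rows) == 3
        np.testing.assert_array_equal(inj_rows, np.zeros((3, 1)))

    def test_athlete_without_injuries_excluded(self):
        X = np.arange(12, dtype=float)[:, None]
        y = np.array([1, 0, 0, 0, 0, 0] + [0] * 6)
        aids = np.array(["a"] * 6 + ["b"] * 6)
        out = R.balanced_per_athlete_sample(X, y, aids, k=2, seed=0)
        assert out.provenance["excluded_athletes"] == ["b"]
        assert len(out.y) == 4

    def test_classes_always_balanced(self):
        X, y, aids = _toy(seed=3)
        out = R.balanced_per_athlete_sample(X, y, aids, k=5, seed=3)
        assert (out.y == 1).sum() == (out.y == 0).sum()

    def test_nonpositive_k_rejected(self):
        X, y, aids = _toy()
        with pytest.raises(ValueError):
            R.balanced_per_athlete_sample(X, y, aids, k=0)


class TestUnbalancedSubsample:
    @pytest.mark.parametrize("n_target,ratio,expected_uninj", [
        (650, 0.136, 4779),  # round(650 / 0.136)
        (10, 0.5, 20),
        (25, 1.0, 25),
    ])
    def test_counts_follow_the_ratio_arithmetic(self, n_target, ratio, expected_uninj):
        X, y, aids = _toy(n_inj=40, n_uninj=60)
        out = R.unbalanced_subsample(X, y, n_target, ratio, seed=2)
        assert (out.y == 1).sum() == n_target
        assert (out.y == 0).sum() == expected_uninj

    def test_bad_ratio_rejected(self):
        X, y, _ = _toy()
        with pytest.raises(ValueError):
            R.unbalanced_subsample(X, y, 10, 0.0)


class TestTomekMajorityRemoval:
    def test_one_dimensional_hand_example(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array([0, 1, 0])
        out = R.tomek_majority_removal(X, y)
        np.testing.assert_array_equal(out.X, [[0.1], [5.0]])
        np.testing.assert_array_equal(out.y, [1, 0])

    def test_separated_classes_unchanged(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.uniform(0, 1, (5, 2)), rng.uniform(10, 11, (20, 2))])
        y = np.array([1] * 5 + [0] * 20)
        out = R.tomek_majority_removal(X, y)
        assert len(out.y) == 25

    def test_minority_count_preserved_and_no_count_grows(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        y = (rng.uniform(size=80) < 0.2).astype(int)
        out = R.tomek_majority_removal(X, y)
        assert (out.y == 1).sum() == (y == 1).sum()
        assert (out.y == 0).sum() <= (y == 0).sum()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            R.tomek_majority_removal(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestSmoteOversample:
    def test_synthetic_points_lie_on_parent_neighbor_segments(self):
        rng = np.random.default_rng(6)
        X = np.concatenate([rng.uniform(size=(12, 2)), rng.uniform(2, 3, (40, 2))])
        y = np.array([1] * 12 + [0] * 40)
        out = R.smote_oversample(X, y, target_minority_count=40, smote_k=3, seed=6)
        assert (out.y == 1).sum() == 40
        new = out.X[len(X):]
        for row, prov in zip(new, out.synthetic):
            d, d_n = X[prov.parent], X[prov.neighbor]
            np.testing.assert_allclose(row, d + prov.u * (d_n - d), atol=1e-12)
            assert 0.0 <= prov.u < 1.0

    def test_convex_hull_membership_on_2d_toy(self):
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(7)
        minority = rng.uniform(size=(15, 2))
        majority = rng.uniform(5, 6, (30, 2))
        X = np.concatenate([minority, majority])
        y = np.array([1] * 15 + [0] * 30)
        out = R.smote_oversample(X, y, target_minority_count=60, smote_k=4, seed=7)
        hull = Delaunay(minority)
        new = out.X[len(X):]
        assert (hull.find_simplex(new) >= 0).all()

    def test_literal_mode_extrapolates_away_from_neighbor(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.2, 0.1], [0.3, 0.1],
                      [5.0, 5.0], [5.1, 5.0], [5.2, 5.0], [5.3, 5.0], [5.4, 5.0]])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0])
        out = R.smote_oversample(X, y, target_minority_count=8, smote_k=2,
                                 seed=8, mode="literal")
        for row, prov in zip(out.X[len(X):], out.synthetic):
            d, d_n = X[prov.parent], X[prov.neighbor]
            np.testing.assert_allclose(row, d + prov.u * (d - d_n), atol=1e-12)

    def test_small_minority_advises_smaller_k(self):
        X, y, _ = _toy(n_inj=3, n_uninj=20)
        with pytest.raises(ValueError, match="smaller k"):
            R.smote_oversample(X, y, target_minority_count=10, smote_k=5)


class TestMultipleResample:
    def test_per_step_counts_match_contracts(self, cohort64):
        X, y, aids, _ = cohort64
        plan = R.ResamplingPlan(seed=1)
        out = R.multiple_resample(X.reshape(len(X), -1), y, aids, plan)
        s1, s2, s3a, s3b = out.provenance["steps"]
        k = out.provenance["plan"]["per_athlete_k"]
        n_kept_athletes = len(np.unique(aids)) - len(s1["excluded_athletes"])
        assert s1["n_injured"] == s1["n_uninjured"] == k * n_kept_athletes
        assert (s2["n_injured"], s2["n_uninjured"]) == (650, 4779)
        assert s3a["n_injured"] == 650  # Tomek never removes minority members
        assert s3a["n_uninjured"] <= 4779
        assert s3b["n_injured"] == s3b["n_uninjured"]  # SMOTE balances at 1:1
        # provenance counts agree with the actual arrays
        assert (out.y == 1).sum() == s3b["n_injured"]
        assert (out.y == 0).sum() == s3b["n_uninjured"]

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(200, 6))
        y = (rng.uniform(size=200) < 0.15).astype(int)
        aids = np.array([f"a{i % 4}" for i in range(200)])
        plan = R.ResamplingPlan(n_injured_target=30, ratio=0.5, smote_k=3, seed=11)
        out1 = R.multiple_resample(X, y, aids, plan)
        out2 = R.multiple_resample(X, y, aids, plan)
        np.testing.assert_array_equal(out1.X, out2.X)
        np.testing.assert_array_equal(out1.y, out2.y)

    def test_cohort_without_injuries_rejected(self):
        X = np.zeros((10, 4))
        y = np.zeros(10, dtype=int)
        aids = np.array(["a"] * 10)
        with pytest.raises(ValueError, match="no injured"):
            R.multiple_resample(X, y, aids, R.ResamplingPlan())

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            R.ResamplingPlan(ratio=1.5)
        with pytest.raises(ValueError):
            R.ResamplingPlan(n_injured_target=0)
        with pytest.raises(ValueError):
            R.ResamplingPlan(smote_mode="midpoint")
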