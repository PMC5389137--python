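"""QDA with thresholding, typicality, separation statistics, resampling."""

import numpy as np
import pytest
from scipy import stats

import caniform as cf
from caniform.classify import UNDETERMINED


def _two_clouds(n=50, sep=10.0, k=3, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n, k))
    b = rng.normal(0, 1, size=(n, k))
    b[:, 0] += sep
    x = np.vstack([a, b])
    y = np.array(["dog"] * n + ["wolf"] * n)
    return x, y


class TestThresholdQDA:
    def test_means_equal_cloud_centroids(self):
        x, y = _two_clouds(seed=1)
        model = cf.fit_qda(x, y)
        np.testing.assert_allclose(model.means_[0], x[y == "dog"].mean(0), atol=1e-12)
        np.testing.assert_allclose(model.means_[1], x[y == "wolf"].mean(0), atol=1e-12)

    def test_1d_posterior_matches_closed_form(self):
        """Two unit-variance Gaussians at ±1 with equal priors."""
        rng = np.random.default_rng(2)
        # large samples so the estimates are near the generating values
        a = rng.normal(-1, 1, size=(20000, 1))
        b = rng.normal(1, 1, size=(20000, 1))
        model = cf.fit_qda(np.vstack([a, b]), np.array(["a"] * 20000 + ["b"] * 20000))
        for x0 in (-2.0, -0.5, 0.0, 1.3):
            p = cf.posterior(model, np.array([x0]))
            da = stats.norm.pdf(x0, model.means_[0][0], np.sqrt(model.covariances_[0][0, 0]))
            db = stats.norm.pdf(x0, model.means_[1][0], np.sqrt(model.covariances_[1][0, 0]))
            assert p[0] == pytest.approx(da / (da + db), abs=1e-12)

    def test_posteriors_sum_to_one(self):
        x, y = _two_clouds(seed=3)
        model = cf.fit_qda(x, y)
        proba = model.predict_proba(np.random.default_rng(4).normal(size=(20, 3)) * 5)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_equidistant_point_is_fifty_fifty(self):
        x, y = _two_clouds(n=4000, sep=4.0, k=2, seed=5)
        model = cf.fit_qda(x, y)
        mid = 0.5 * (model.means_[0] + model.means_[1])
        # force exact symmetry: equal covariances and equal distances
        model.covariances_[1] = model.covariances_[0]
        p = cf.posterior(model, mid)
        assert p[0] == pytest.approx(0.5, abs=1e-10)

    def test_point_at_group_mean_is_decisive(self):
        x, y = _two_clouds(n=200, sep=10.0, seed=6)
        model = cf.fit_qda(x, y)
        p = cf.posterior(model, model.means_[0])
        assert p[0] > 0.999

    def test_overlapping_groups_posterior_near_half_at_shared_mean(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(400, 3))
        y = np.array(["a", "b"] * 200)
        model = cf.fit_qda(x, y)
        p = cf.posterior(model, np.zeros(3))
        assert p[0] == pytest.approx(0.5, abs=0.1)

    def test_small_group_for_dimension_raises(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 6))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="fewer PCs"):
            cf.fit_qda(x, y)

    def test_matches_sklearn_qda_posteriors(self):
        """Cross-check against the reference discriminant implementation."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        x, y = _two_clouds(n=80, sep=3.0, k=4, seed=9)
        mine = cf.fit_qda(x, y)
        ref = QuadraticDiscriminantAnalysis(
            priors=[0.5, 0.5], store_covariance=True
        ).fit(x, y)
        grid = np.random.default_rng(10).normal(size=(30, 4)) * 3
        np.testing.assert_allclose(
            mine.predict_proba(grid), ref.predict_proba(grid), atol=1e-8
        )


class TestThresholdRule:
    @pytest.mark.parametrize("post,expected", [
        ((0.95, 0.05), "dog"),
        ((0.60, 0.40), UNDETERMINED),
        ((0.90, 0.10), UNDETERMINED),  # strictly greater than 0.90
        ((0.05, 0.95), "wolf"),
        ((0.5, 0.5), UNDETERMINED),
    ])
    def test_threshold_examples(self, post, expected):
        classes = np.array(["dog", "wolf"])
        assert cf.classify_threshold(np.array(post), classes, 0.90) == expected


class TestSeparationStatistics:
    def test_tau_perfect_classification(self):
        conf = np.array([[50, 0], [0, 50]])
        assert cf.klecka_tau(conf, [0.5, 0.5], [50, 50]) == pytest.approx(1.0)

    def test_tau_chance_level(self):
        conf = np.array([[25, 25], [25, 25]])
        assert cf.klecka_tau(conf, [0.5, 0.5], [50, 50]) == pytest.approx(0.0)

    def test_tau_96_percent_correct(self):
        conf = np.array([[48, 2], [2, 48]])
        assert cf.klecka_tau(conf, [0.5, 0.5], [50, 50]) == pytest.approx(0.92)

    def test_wilks_identical_means_near_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(200, 4))
        y = np.array(["a", "b"] * 100)
        assert cf.wilks_lambda(x, y) > 0.9

    def test_wilks_separated_groups_near_zero(self):
        x, y = _two_clouds(n=100, sep=50.0, seed=12)
        assert cf.wilks_lambda(x, y) < 0.01

    def test_wilks_matches_explicit_sscp_oracle(self):
        x, y = _two_clouds(n=60, sep=2.0, k=4, seed=13)
        # independent oracle: explicit determinant ratio
        grand = x.mean(0)
        t = sum(np.outer(r - grand, r - grand) for r in x)
        w = np.zeros((4, 4))
        for g in ("dog", "wolf"):
            m = x[y == g].mean(0)
            w += sum(np.outer(r - m, r - m) for r in x[y == g])
        oracle = np.linalg.det(w) / np.linalg.det(t)
        assert cf.wilks_lambda(x, y) == pytest.approx(oracle, rel=1e-10)


class TestBoxM:
    def test_df_for_two_groups_seven_variables(self):
        x, y = _two_clouds(n=60, sep=1.0, k=7, seed=14)
        _, df, _ = cf.box_m(x, y)
        assert df == 28

    def test_identical_group_data_gives_zero_statistic(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=(40, 3))
        x = np.vstack([a, a])
        y = np.array(["a"] * 40 + ["b"] * 40)
        m, _, p = cf.box_m(x, y)
        assert m == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(16)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=(400, 5))
            y = np.array(["a"] * 200 + ["b"] * 200)
            _, _, p = cf.box_m(x, y)
            if p <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se


class TestTypicality:
    def test_at_group_mean_typicality_is_one(self):
        cov = np.eye(3)
        assert cf.typicality(cov, np.zeros(3), np.zeros(3), df=3) == pytest.approx(1.0)

    def test_quantile_inversion(self):
        d2 = stats.chi2.ppf(0.95, df=7)
        x = np.zeros(7)
        x[0] = np.sqrt(d2)
        assert cf.typicality(np.eye(7), np.zeros(7), x, df=7) == pytest.approx(0.05, abs=1e-12)

    def test_matches_chi_square_cdf_oracle(self):
        rng = np.random.default_rng(17)
        cov = np.eye(4) * 2.0
        mean = rng.normal(size=4)
        for _ in range(10):
            x = rng.normal(size=4) * 3
            d = x - mean
            d2 = d @ np.linalg.inv(cov) @ d
            oracle = 1.0 - stats.chi2.cdf(d2, 4)
            assert cf.typicality(cov, mean, x, df=4) == pytest.approx(oracle, abs=1e-12)


class TestLoocv:
    def test_well_separated_groups_fully_correct(self):
        x, y = _two_clouds(n=50, sep=10.0, seed=18)
        summary = cf.loocv_summary(x, y)
        assert summary.percent_correct == 100.0
        assert summary.tau == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(19)
        x, y = _two_clouds(n=100, sep=5.0, seed=20)
        y = rng.permutation(y)
        summary = cf.loocv_summary(x, y, threshold=0.5)
        assert summary.percent_correct < 65.0
        assert abs(summary.tau) < 0.3

    def test_moving_one_specimen_changes_count_by_one_share(self):
        x, y = _two_clouds(n=50, sep=12.0, seed=21)
        base = cf.loocv_summary(x, y).percent_correct
        x2 = x.copy()
        x2[0] = x[y == "wolf"].mean(0)  # drop a dog into the wolf cloud
        moved = cf.loocv_summary(x2, y).percent_correct
        assert base - moved == pytest.approx(100.0 / len(x), abs=1e-9)


class TestResampledQDA:
    def _forms(self, seed=22, n_dog=40, n_wolf=80, sep=8.0, k=6):
        rng = np.random.default_rng(seed)
        dogs = rng.normal(0, 1, size=(n_dog, k))
        wolves = rng.normal(0, 1, size=(n_wolf, k))
        wolves[:, 0] += sep
        x = np.vstack([dogs, wolves])
        y = np.array(["dog"] * n_dog + ["wolf"] * n_wolf)
        return x, y

    def test_dog_unknowns_called_dog(self):
        x, y = self._forms()
        rng = np.random.default_rng(23)
        unknowns = rng.normal(0, 1, size=(3, 6))  # from the dog distribution
        report, summary = cf.resampled_classification(
            x, y, unknowns, n_iter=50, seed=7
        )
        for call in report.calls:
            assert call.final_call == "Dog"
            assert call.percent_calls["dog"] >= 90.0
        assert summary.percent_correct > 95.0

    def test_midpoint_unknown_is_indeterminate(self):
        x, y = self._forms(sep=6.0)
        mid = np.zeros((1, 6))
        mid[0, 0] = 3.0  # halfway between the group means
        report, _ = cf.resampled_classification(x, y, mid, n_iter=50, seed=8)
        assert report.calls[0].final_call == "Ind"
        assert report.calls[0].percent_calls[UNDETERMINED] > 20.0

    def test_identical_seed_gives_identical_report(self):
        x, y = self._forms()
        u = np.random.default_rng(24).normal(size=(2, 6))
        r1, s1 = cf.resampled_classification(x, y, u, n_iter=25, seed=11)
        r2, s2 = cf.resampled_classification(x, y, u, n_iter=25, seed=11)
        assert r1.to_frame().equals(r2.to_frame())
        assert s1.percent_correct == s2.percent_correct
        assert s1.box_m == s2.box_m

    def test_outcome_percentages_sum_to_hundred(self):
        x, y = self._forms(sep=2.0)
        u = np.random.default_rng(25).normal(size=(4, 6)) * 2
        report, _ = cf.resampled_classification(x, y, u, n_iter=40, seed=12)
        for call in report.calls:
            total = sum(call.percent_calls.values())
            assert total == pytest.approx(100.0, abs=1e-9)
            assert sum(call.mean_posterior.values()) == pytest.approx(1.0, abs=1e-10)

    def test_more_dogs_than_wolves_rejected(self):
        x, y = self._forms(n_dog=50, n_wolf=30)
        model = cf.ResampledQDA(n_iter=5)
        with pytest.raises(ValueError, match="at least as many wolves"):
            model.fit(x, y)
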