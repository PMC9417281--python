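"""Gaussian-mixture soft classification: EM correctness, class-count
selection, responsibilities and weighted summaries."""

import numpy as np
import pandas as pd
import pytest

from nanoshape.classify import (
    Classification,
    bic,
    class_summary,
    fit_gmm,
    select_classes,
    soft_assign,
)


def two_cluster_data(rng, n=400, sep=10.0):
    n1 = n // 2
    x1 = rng.normal(0, 1, size=(n1, 2))
    x2 = rng.normal(0, 1, size=(n - n1, 2)) + sep
    return np.vstack([x1, x2]), n1


class TestFitGMM:
    def test_single_component_is_mle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 2)) @ np.array([[1.0, 0.4], [0.0, 0.6]])
        m = fit_gmm(X, 1)
        np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(
            m.covariances[0], np.cov(X.T, bias=True), atol=1e-6
        )
        assert m.weights[0] == 1.0

    def test_well_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        X, n1 = two_cluster_data(rng)
        m = fit_gmm(X, 2, seed=0)
        cls = soft_assign(m, X)
        assert np.mean(cls.responsibilities.max(axis=1) > 0.99) > 0.99
        assert sorted(np.round(m.weights, 2)) == pytest.approx([0.5, 0.5], abs=0.03)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        X, _ = two_cluster_data(rng, sep=2.0)
        for seed in range(5):
            m = fit_gmm(X, 3, seed=seed, n_restarts=2)
            diffs = np.diff(m.ll_history)
            assert np.all(diffs >= -1e-6 * np.abs(m.ll_history[:-1]))

    def test_bit_identical_determinism(self):
        rng = np.random.default_rng(3)
        X, _ = two_cluster_data(rng, sep=3.0)
        m1 = fit_gmm(X, 2, seed=7)
        m2 = fit_gmm(X, 2, seed=7)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.covariances, m2.covariances)
        assert m1.loglik == m2.loglik

    def test_matches_sklearn_reference(self):
        """Independent cross-check: same data, compare converged solution
        against sklearn's EM implementation."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        X, _ = two_cluster_data(rng, sep=6.0)
        ours = fit_gmm(X, 2, seed=0)
        ref = GaussianMixture(2, covariance_type="full", n_init=5,
                              random_state=0, tol=1e-8).fit(X)
        np.testing.assert_allclose(
            np.sort(ours.means, axis=0), np.sort(ref.means_, axis=0), atol=0.05
        )
        np.testing.assert_allclose(
            np.sort(ours.weights), np.sort(ref.weights_), atol=0.02
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((4, 2)), 2)


class TestSelectClasses:
    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 2))
        assert select_classes(X, K_max=5, seed=0).K == 1

    def test_two_separated_clusters_select_two(self):
        rng = np.random.default_rng(6)
        X, _ = two_cluster_data(rng, sep=8.0)
        assert select_classes(X, K_max=5, seed=0).K == 2

    def test_weight_prune_criterion(self):
        rng = np.random.default_rng(7)
        X, _ = two_cluster_data(rng, sep=8.0)
        m = select_classes(X, K_max=5, criterion="weight_prune",
                           prune_weight=0.05, seed=0)
        assert m.K == 2

    def test_overlapping_two_component_selection_rate(self):
        """On moderately overlapping two-component data the selected K
        should be 2 in at least 90% of seeded replicates."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n1 = rng.binomial(500, 0.55)
            X = np.vstack(
                [
                    rng.normal([0, 0], [0.8, 1.0], size=(n1, 2)),
                    rng.normal([3.5, 2.5], [1.0, 0.9], size=(500 - n1, 2)),
                ]
            )
            m = select_classes(X, K_max=4, seed=rep, n_restarts=3)
            hits += m.K == 2
        assert hits >= 0.9 * reps

    def test_bic_penalizes_complexity(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 2))
        m1 = fit_gmm(X, 1)
        m3 = fit_gmm(X, 3, seed=0)
        assert bic(m1, X) < bic(m3, X)


class TestSoftAssign:
    def test_point_at_component_mean(self):
        m = fit_gmm(
            np.vstack([np.random.default_rng(0).normal(0, 1, (50, 2)),
                       np.random.default_rng(1).normal(200, 1, (50, 2))]),
            2, seed=0,
        )
        far = np.argmax(m.means[:, 0])
        cls = soft_assign(m, m.means[[far]])
        assert cls.responsibilities[0, far] == pytest.approx(1.0, abs=1e-10)

    def test_equidistant_symmetric_point(self):
        model = fit_gmm(np.array([[0.0, 0.0]] * 30 + [[2.0, 0.0]] * 30), 1)
        # build a symmetric 2-component model by hand
        from nanoshape.classify import MixtureModel

        sym = MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [2.0, 0.0]]),
            covariances=np.array([np.eye(2), np.eye(2)]),
            loglik=0.0, ll_history=np.array([0.0]), n_iter=1,
        )
        cls = soft_assign(sym, np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(cls.responsibilities[0], [0.5, 0.5], atol=1e-12)

    def test_rows_sum_to_one_and_totals_conserve(self):
        rng = np.random.default_rng(9)
        X, _ = two_cluster_data(rng, sep=1.0)
        cls = soft_assign(fit_gmm(X, 3, seed=0), X)
        np.testing.assert_allclose(cls.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert cls.class_totals.sum() == pytest.approx(len(X), abs=1e-8)
        assert np.all(np.isfinite(cls.responsibilities))

    def test_extreme_outlier_never_nan(self):
        rng = np.random.default_rng(10)
        X, _ = two_cluster_data(rng, sep=2.0)
        m = fit_gmm(X, 2, seed=0)
        cls = soft_assign(m, np.array([[1e6, -1e6]]))
        assert np.all(np.isfinite(cls.responsibilities))
        assert cls.responsibilities.sum() == pytest.approx(1.0)


class TestClassSummary:
    def test_hard_responsibility_example(self):
        cls = Classification(np.array([[1, 0], [1, 0], [0, 1]], float))
        df = pd.DataFrame({"d_eff_nm": [10.0, 12.0, 20.0], "AR": [1, 1, 2.0]})
        s = class_summary(cls, df)
        assert s["sigma"].tolist() == [2.0, 1.0]
        assert s["fraction"].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert s["diam_mean_nm"].tolist() == pytest.approx([11.0, 20.0])

    def test_uniform_mixing_gives_global_means(self):
        cls = Classification(np.full((6, 2), 0.5))
        df = pd.DataFrame({"d_eff_nm": np.arange(6.0), "AR": np.ones(6)})
        s = class_summary(cls, df)
        assert s["diam_mean_nm"].tolist() == pytest.approx([2.5, 2.5])

    def test_empty_class_reports_null_stats(self):
        cls = Classification(np.array([[1.0, 0.0], [1.0, 0.0]]))
        df = pd.DataFrame({"d_eff_nm": [5.0, 7.0], "AR": [1.0, 1.0]})
        s = class_summary(cls, df)
        assert np.isnan(s.loc[s["sigma"] == 0.0, "diam_mean_nm"]).all()

    def test_summary_sorted_by_total_responsibility(self):
        cls = Classification(np.array([[0, 1], [0, 1], [1, 0]], float))
        df = pd.DataFrame({"d_eff_nm": [1.0, 2, 3], "AR": [1.0, 1, 1]})
        s = class_summary(cls, df)
        assert s["k"].tolist() == [1, 2]
        assert s["sigma"].is_monotonic_decreasing

    def test_overlapping_continuum_recovers_class_ar_means(self):
        """Irregular rounded-shape continuum (two overlapping AR classes):
        responsibility-weighted class AR means recover the generating
        class means within +/-0.03."""
        from nanoshape.descriptors import describe_all, descriptor_table
        from nanoshape.synthetic import make_ensemble, packed_qd_spec

        sc = make_ensemble(packed_qd_spec(270, 212), seed=2, render=False,
                           image_shape=(4000, 4000))
        df = descriptor_table(describe_all(sc.truth_contours))
        X = df[["logH1", "logH2"]].to_numpy()
        m = fit_gmm(X, 2, seed=0)
        s = class_summary(soft_assign(m, X), df).sort_values("AR_mean")
        truth = sc.truth_params.groupby("label")["aspect_ratio"].mean().sort_values()
        np.testing.assert_allclose(
            s["AR_mean"].to_numpy(), truth.to_numpy(), atol=0.03
        )
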