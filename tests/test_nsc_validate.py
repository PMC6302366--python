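import numpy as np
import pytest

from paretosig.data_io import ExpressionMatrix, GroupLabels
from paretosig.nsc_validate import (
    _metrics,
    cv_select_delta,
    evaluate_signature,
    fit_nsc,
    predict_nsc,
)
from paretosig.synthetic import SyntheticConfig, generate

from conftest import make_groups, make_matrix


def random_dataset(seed, n_genes=10, n_per_class=10, shift=0.0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_genes, 2 * n_per_class))
    vals[:, n_per_class:] += shift
    X = make_matrix(vals)
    return X, make_groups(X.sample_ids, n_per_class)


class TestFitNsc:
    def test_delta_zero_keeps_class_centroids(self):
        X, y = random_dataset(0)
        m = fit_nsc(X, y, delta=0.0)
        np.testing.assert_allclose(m.shrunken_centroids, m.class_centroids, atol=1e-12)

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        X, y = random_dataset(1)
        m0 = fit_nsc(X, y, delta=0.0)
        m = fit_nsc(X, y, delta=float(np.abs(m0.d).max()) + 1e-9)
        assert np.all(m.d_shrunk == 0)
        for k in (0, 1):
            np.testing.assert_allclose(
                m.shrunken_centroids[:, k], m.overall_centroid, atol=1e-12
            )

    def test_one_gene_hand_example(self):
        X = ExpressionMatrix(
            ["g1"], ["a", "b", "c", "d"], np.array([[1.0, 3.0, 5.0, 7.0]]), "other"
        )
        y = GroupLabels({"a": "control", "b": "control", "c": "case", "d": "case"})
        m = fit_nsc(X, y, delta=1.0)
        assert m.overall_centroid[0] == 4.0
        np.testing.assert_allclose(m.pooled_sd[0], np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(m.m_k, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(m.d[0, 0], -np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(m.d_shrunk[0, 0], 1 - np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(m.shrunken_centroids[0, 0], 2 + np.sqrt(2), atol=1e-9)

    def test_single_class_training_rejected(self):
        X, _ = random_dataset(2)
        y = GroupLabels({s: "case" for s in X.sample_ids})
        with pytest.raises(ValueError):
            fit_nsc(X, y, delta=0.0)

    def test_shrinkage_monotone_in_delta(self):
        X, y = random_dataset(3, n_genes=50)
        m0 = fit_nsc(X, y, delta=0.0)
        deltas = np.linspace(0, np.abs(m0.d).max() * 1.1, 15)
        active = [fit_nsc(X, y, delta=d).n_active_genes for d in deltas]
        assert all(a >= b for a, b in zip(active, active[1:]))


class TestPredictNsc:
    def test_sample_at_centroid_classified_to_it(self):
        X, y = random_dataset(4, shift=1.0)
        m = fit_nsc(X, y, delta=0.0)  # balanced classes -> equal priors
        for k in (0, 1):
            pred, _ = predict_nsc(m, m.shrunken_centroids[:, [k]])
            assert pred[0] == k

    def test_fully_shrunk_model_predicts_larger_prior(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(8, 12))
        X = make_matrix(vals)
        y = make_groups(X.sample_ids, 3)  # 3 control vs 9 case
        m0 = fit_nsc(X, y, delta=0.0)
        m = fit_nsc(X, y, delta=float(np.abs(m0.d).max()) + 1.0)
        pred, _ = predict_nsc(m, rng.normal(size=(8, 30)))
        assert (pred == 1).all()  # case has the larger prior

    def test_separable_training_data_perfectly_refit(self):
        X, y = random_dataset(6, n_genes=5, shift=6.0)
        m = fit_nsc(X, y, delta=0.0)
        pred, _ = predict_nsc(m, X.values)
        np.testing.assert_array_equal(pred, y.labels_for(X.sample_ids))

    def test_delta_zero_equals_standardized_nearest_centroid(self):
        # balanced classes: priors cancel; oracle = argmin_k sum_i
        # (x_i - centroid_ik)^2 / (s_i + s0)^2, computed independently here
        for seed in range(20):
            X, y = random_dataset(seed, n_genes=15, n_per_class=6,
                                  shift=float(seed % 3))
            m = fit_nsc(X, y, delta=0.0)
            lab = y.labels_for(X.sample_ids)
            cen = np.stack([X.values[:, lab == 0].mean(1), X.values[:, lab == 1].mean(1)], 1)
            ss = sum(((X.values[:, lab == k] - cen[:, [k]]) ** 2).sum(1) for k in (0, 1))
            scale = np.sqrt(ss / (X.n_samples - 2))
            scale = scale + np.median(scale)
            rng = np.random.default_rng(1000 + seed)
            Q = rng.normal(size=(15, 25))
            want = np.argmin(
                [(((Q - cen[:, [k]]) / scale[:, None]) ** 2).sum(0) for k in (0, 1)],
                axis=0,
            )
            got, _ = predict_nsc(m, Q)
            np.testing.assert_array_equal(got, want)


class TestCvSelectDelta:
    def test_separable_data_zero_error_positive_delta(self):
        X, y = random_dataset(7, n_genes=20, n_per_class=15, shift=5.0)
        delta_star, curve = cv_select_delta(X, y, folds=5, seed=0)
        assert curve["cv_error"].min() == 0.0
        assert delta_star > 0.0

    def test_grid_of_length_one(self):
        X, y = random_dataset(8, n_per_class=5)
        delta_star, curve = cv_select_delta(X, y, delta_grid=np.array([0.37]), folds=3, seed=0)
        assert delta_star == 0.37
        assert len(curve) == 1

    def test_deterministic_given_seed(self):
        X, y = random_dataset(9, n_per_class=8)
        a = cv_select_delta(X, y, folds=4, seed=11)
        b = cv_select_delta(X, y, folds=4, seed=11)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1]["cv_error"], b[1]["cv_error"])

    def test_minority_class_too_small(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(5, 6)))
        y = GroupLabels({s: ("control" if i == 0 else "case")
                         for i, s in enumerate(X.sample_ids)})
        with pytest.raises(ValueError, match="minority"):
            cv_select_delta(X, y, folds=3, seed=0)


class TestEvaluateSignature:
    def test_confusion_metric_definitions(self):
        m = _metrics(tp=9, fp=2, tn=8, fn=1)
        assert m["sensitivity"] == 0.9
        assert m["specificity"] == 0.8
        np.testing.assert_allclose(m["precision"], 9 / 11)
        assert m["accuracy"] == 17 / 20

    def test_planted_signature_high_accuracy(self):
        X, groups, truth = generate(
            SyntheticConfig(
                n_genes=35, n_control=20, n_case=50, n_modules=1,
                genes_per_module=35, within_module_rho=0.2, de_fraction=1.0,
                log2_effect=1.5, count_model="gaussian_log", seed=10,
            )
        )
        report = evaluate_signature(X, groups, repeats=10, folds=10, seed=0)
        assert report.summary.loc["accuracy", "mean"] >= 0.9

    def test_null_signature_near_majority_rate(self):
        rng = np.random.default_rng(11)
        X = make_matrix(rng.normal(size=(20, 60)))
        y = make_groups(X.sample_ids, 24)  # majority frequency 0.6
        report = evaluate_signature(X, y, repeats=10, folds=6, seed=1)
        assert abs(report.summary.loc["accuracy", "mean"] - 0.6) <= 0.1

    def test_invariant_to_sample_column_order(self):
        X, y = random_dataset(12, n_genes=8, n_per_class=10, shift=1.0)
        perm = np.random.default_rng(13).permutation(X.n_samples)
        X_shuf = X.subset_samples([X.sample_ids[i] for i in perm])
        a = evaluate_signature(X, y, repeats=3, folds=4, seed=2)
        b = evaluate_signature(X_shuf, y, repeats=3, folds=4, seed=2)
        assert a.per_repeat[["TP", "FP", "TN", "FN"]].equals(
            b.per_repeat[["TP", "FP", "TN", "FN"]]
        )
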