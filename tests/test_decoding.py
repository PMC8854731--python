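import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinedecode.decoding import (
    LabeledDataset,
    crossval_experiment,
    evaluate_regression,
    fit_bayesian_regression,
    fit_linear_svm,
    fit_pcr,
    make_folds,
    predict,
)


def make_dataset(X, labels_dict, participants=None):
    n = X.shape[0]
    participants = participants or [f"P{i:03d}" for i in range(n)]
    ids = [(p, "S00") for p in participants]
    labels = pd.DataFrame(labels_dict, index=pd.Index(list(dict.fromkeys(participants))))
    return LabeledDataset(features=X, sample_ids=ids, labels=labels)


class TestMakeFolds:
    def test_balanced_partition(self):
        fa = make_folds(10, k=5, seed=0)
        assert sorted(np.bincount(fa.fold_index)) == [2, 2, 2, 2, 2]

    def test_deterministic(self):
        a = make_folds(23, k=5, seed=7)
        b = make_folds(23, k=5, seed=7)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    def test_seed_changes_assignment(self):
        a = make_folds(50, k=5, seed=1)
        b = make_folds(50, k=5, seed=2)
        assert (a.fold_index != b.fold_index).any()

    def test_grouped_mode_keeps_participants_together(self):
        groups = np.repeat([f"P{i}" for i in range(10)], 4)
        fa = make_folds(40, k=5, seed=3, groups=groups)
        assert fa.mode == "grouped"
        for g in np.unique(groups):
            assert np.unique(fa.fold_index[groups == g]).size == 1

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            make_folds(3, k=5, seed=0)

    def test_too_few_groups_errors(self):
        with pytest.raises(ValueError):
            make_folds(10, k=5, seed=0, groups=np.repeat(["a", "b"], 5))


class TestLinearSVM:
    def test_symmetric_pair_boundary_at_zero(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = fit_linear_svm(X, y)
        assert abs(model.intercept) < 1e-6
        assert model.decision_values(np.array([[-1.0]]))[0] < 0
        assert model.decision_values(np.array([[1.0]]))[0] > 0

    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.5, size=(30, 2)), rng.normal(5, 0.5, size=(30, 2))])
        y = np.repeat([0, 1], 30)
        model = fit_linear_svm(X, y)
        pred = (model.decision_values(X) > 0).astype(int)
        assert (pred == y).all()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_linear_svm(np.zeros((4, 2)), np.zeros(4))

    def test_permuted_labels_near_majority_rate(self):
        # permutation-null oracle: accuracy within the central 99% binomial band
        rng = np.random.default_rng(42)
        n, p_maj = 100, 0.6
        X = rng.normal(size=(n, 20))
        y = np.array(["a"] * 60 + ["b"] * 40)
        rng.shuffle(y)
        data = make_dataset(X, {"gender": y}, participants=[f"P{i}" for i in range(n)])
        folds = make_folds(n, k=5, seed=0)
        ev, _ = crossval_experiment(data, "gender", "svm", folds)
        lo, hi = stats.binom.interval(0.99, n, p_maj)
        assert lo / n <= ev.mean_accuracy <= hi / n


class TestBayesianRegression:
    def test_noiseless_linear_target(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = 2.0 * X[:, 0] + 1.0
        model = fit_bayesian_regression(X[:40], y[:40])
        r2, _ = evaluate_regression(y[40:], model.decision_values(X[40:]))
        assert r2 >= 0.99

    def test_constant_target_intercept_only(self):
        X = np.random.default_rng(2).normal(size=(10, 4))
        model = fit_bayesian_regression(X, np.full(10, 3.0))
        np.testing.assert_allclose(model.weights, 0.0)
        np.testing.assert_allclose(model.decision_values(X), 3.0)

    def test_predictive_std_grows_with_extrapolation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 1))
        y = 1.5 * X[:, 0] + rng.normal(scale=0.1, size=40)
        model = fit_bayesian_regression(X, y)
        centre = np.array([[X.mean()]])
        far = np.array([[X.mean() + 50 * X.std()]])
        _, std_centre = predict(model, centre, return_std=True)
        _, std_far = predict(model, far, return_std=True)
        assert std_far[0] > std_centre[0]

    def test_conjugate_closed_form_oracle_1d(self):
        # known-precision Bayesian linear regression has a closed form;
        # the evidence-maximized fit should land near it on well-behaved data
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 1))
        y = 3.0 * X[:, 0] + rng.normal(scale=0.5, size=200)
        model = fit_bayesian_regression(X, y)
        est = model.extra["estimator"]
        Xc = X - X.mean(axis=0)
        A = est.lambda_ * np.eye(1) + est.alpha_ * Xc.T @ Xc
        w_closed = est.alpha_ * np.linalg.solve(A, Xc.T @ (y - y.mean()))
        assert model.weights[0] == pytest.approx(w_closed[0], rel=1e-6)


class TestPCR:
    def test_rank_one_keeps_one_component(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=4)
        X = rng.normal(size=(30, 1)) @ direction[None, :]
        y = X[:, 0] * 2.0
        model = fit_pcr(X, y, variance_kept=0.95)
        assert model.extra["n_components"] == 1

    def test_variance_one_equals_ols(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        model = fit_pcr(X, y, variance_kept=1.0)
        beta, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(50)]), y, rcond=None)
        np.testing.assert_allclose(model.decision_values(X), X @ beta[:4] + beta[4], atol=1e-8)

    def test_weight_vector_reproduces_component_fit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        model = fit_pcr(X, y, variance_kept=0.9)
        # algebraic identity: full-space affine form equals component-space fit
        mean = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mean, full_matrices=False)
        Vt = Vt[: model.extra["n_components"]]
        Z = (X - mean) @ Vt.T
        from sklearn.linear_model import LinearRegression

        ols = LinearRegression().fit(Z, y)
        np.testing.assert_allclose(model.decision_values(X), ols.predict(Z), atol=1e-10)

    def test_bad_variance_kept_errors(self):
        with pytest.raises(ValueError):
            fit_pcr(np.zeros((5, 2)), np.zeros(5), variance_kept=1.5)


class TestEvaluateRegression:
    def test_perfect_fit(self):
        assert evaluate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (1.0, 0.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = evaluate_regression(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_example(self):
        r2, rmse = evaluate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_regression([2.0, 2.0], [1.0, 3.0])


class TestCrossvalExperiment:
    @pytest.fixture
    def regression_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.05, size=40)
        return make_dataset(X, {"extraversion": y}, [f"P{i}" for i in range(40)])

    def test_five_models_returned(self, regression_data):
        folds = make_folds(40, k=5, seed=0)
        ev, models = crossval_experiment(regression_data, "extraversion", "bayesian", folds)
        assert len(models) == 5
        assert [m.fold for m in models] == [0, 1, 2, 3, 4]

    def test_means_are_arithmetic_means(self, regression_data):
        folds = make_folds(40, k=5, seed=0)
        ev, _ = crossval_experiment(regression_data, "extraversion", "bayesian", folds)
        assert ev.mean_r2 == pytest.approx(np.mean(ev.per_fold_r2))
        assert ev.mean_rmse == pytest.approx(np.mean(ev.per_fold_rmse))

    def test_reproducible(self, regression_data):
        folds = make_folds(40, k=5, seed=0)
        ev1, m1 = crossval_experiment(regression_data, "extraversion", "bayesian", folds)
        ev2, m2 = crossval_experiment(regression_data, "extraversion", "bayesian", folds)
        assert ev1.per_fold_r2 == ev2.per_fold_r2
        np.testing.assert_array_equal(m1[0].weights, m2[0].weights)

    def test_family_target_mismatch_errors(self, regression_data):
        folds = make_folds(40, k=5, seed=0)
        with pytest.raises(ValueError):
            crossval_experiment(regression_data, "extraversion", "svm", folds)

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(9)
        n = 30
        X = rng.normal(size=(n, 4))
        y = np.where(X[:, 0] > 0, "female", "male")
        X[:, 0] += 3 * (y == "female")
        data = make_dataset(X, {"gender": y}, [f"P{i}" for i in range(n)])
        folds = make_folds(n, k=5, seed=1)
        ev, _ = crossval_experiment(data, "gender", "svm", folds)
        assert ev.confusion_counts.sum() == n

    @pytest.mark.parametrize("family", ["bayesian", "pcr"])
    def test_realizable_target_high_r2(self, family):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 3.0
        data = make_dataset(X, {"openness": y}, [f"P{i}" for i in range(60)])
        folds = make_folds(60, k=5, seed=2)
        ev, _ = crossval_experiment(data, "openness", family, folds)
        assert ev.mean_r2 >= 0.99

    def test_permuted_target_r2_near_zero(self):
        # expectation over 20 seeds of held-out R^2 on pure noise targets
        rng = np.random.default_rng(11)
        r2s = []
        for seed in range(20):
            X = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            data = make_dataset(X, {"openness": y}, [f"P{i}" for i in range(30)])
            folds = make_folds(30, k=5, seed=seed)
            ev, _ = crossval_experiment(data, "openness", "bayesian", folds)
            r2s.append(ev.mean_r2)
        assert np.mean(r2s) <= 0.05
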