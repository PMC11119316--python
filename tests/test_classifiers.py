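import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gazexplore import (
    CVConfig,
    DataError,
    LambdaThresholdClassifier,
    confusion_metrics,
    cross_validate,
    feature_importance_order,
    fit_lambda_threshold,
    fit_logistic,
    predict_proba,
)
from gazexplore.classifiers import Grouping, LogisticModel, ThresholdDirection


def toy_table(x, labels, name="f"):
    return pd.DataFrame({name: np.asarray(x, float)}), np.asarray(labels, int)


class TestLogistic:
    def test_midpoint_probability(self):
        model = LogisticModel(beta0=0.0, betas={"f": 0.0}, normalization={"f": (0.0, 1.0)})
        p = predict_proba(model, pd.DataFrame({"f": [1.0, -3.0]}))
        np.testing.assert_allclose(p, 0.5)

    def test_intercept_log_three(self):
        model = LogisticModel(beta0=math.log(3), betas={"f": 0.0}, normalization={"f": (0.0, 1.0)})
        p = predict_proba(model, pd.DataFrame({"f": [0.0]}))
        assert p[0] == pytest.approx(0.75)

    def test_probability_increasing_in_linear_predictor(self):
        model = LogisticModel(beta0=0.5, betas={"f": 2.0}, normalization={"f": (0.0, 1.0)})
        p = predict_proba(model, pd.DataFrame({"f": np.linspace(-3, 3, 20)}))
        assert np.all(np.diff(p) > 0)

    def test_no_signal_gives_zero_slopes(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0], "g": [0.0, 1.0, 0.0, 1.0]})
        model = fit_logistic(X, [0, 0, 1, 1], feature_names=("f", "g"))
        assert abs(model.betas["f"]) < 1e-6
        assert abs(model.betas["g"]) < 1e-6

    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"signal": y * 2.0 + rng.normal(0, 0.3, n), "noise": rng.normal(size=n)})
        model = fit_logistic(X, y, feature_names=("signal", "noise"))
        assert abs(model.betas["signal"]) > abs(model.betas["noise"])

    def test_mean_probability_equals_class_fraction(self):
        rng = np.random.default_rng(4)
        n = 50
        y = (rng.random(n) < 0.4).astype(int)
        if len(np.unique(y)) < 2:  # pragma: no cover - guard, not expected
            y[0] = 1 - y[0]
        X = pd.DataFrame({"f": rng.normal(size=n) + 0.5 * y, "g": rng.normal(size=n)})
        model = fit_logistic(X, y, feature_names=("f", "g"))
        p = predict_proba(model, X)
        assert p.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_matches_independent_optimizer_on_six_trials(self):
        X, y = toy_table([0, 1, 2, 3, 4, 5], [0, 0, 1, 0, 1, 1])
        model = fit_logistic(X, y, feature_names=("f",))

        z = (X["f"].to_numpy() - X["f"].mean()) / X["f"].std(ddof=0)

        def nll(b):
            L = b[0] + b[1] * z
            return float(np.sum(np.logaddexp(0, -L) * y + np.logaddexp(0, L) * (1 - y)))

        oracle = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-14})
        ours = nll([model.beta0, model.betas["f"]])
        assert ours == pytest.approx(oracle.fun, abs=1e-6)

    def test_perfect_separation_is_flagged(self):
        X, y = toy_table([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        model = fit_logistic(X, y, feature_names=("f",), max_iter=50)
        assert model.separation_flagged
        assert np.isfinite(model.betas["f"])

    def test_missing_feature_column_is_usage_error(self):
        model = LogisticModel(beta0=0.0, betas={"f": 1.0}, normalization={"f": (0.0, 1.0)})
        with pytest.raises(DataError, match="missing feature"):
            predict_proba(model, pd.DataFrame({"g": [1.0]}))


class TestFeatureImportance:
    def test_informative_feature_ranked_first_both_ways(self):
        rng = np.random.default_rng(9)
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"signal": y * 3.0 + rng.normal(0, 0.5, n), "noise": rng.normal(size=n)})
        model = fit_logistic(X, y, feature_names=("signal", "noise"))
        ranks = feature_importance_order(model, X, y, seed=0)
        assert ranks.loc["signal", "rank_beta"] == 1
        assert ranks.loc["signal", "rank_perm"] == 1

    def test_pure_noise_feature_has_negligible_importance(self):
        rng = np.random.default_rng(9)
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"signal": y * 3.0 + rng.normal(0, 0.5, n), "noise": rng.normal(size=n)})
        model = fit_logistic(X, y, feature_names=("signal", "noise"))
        ranks = feature_importance_order(model, X, y, seed=0)
        assert abs(ranks.loc["noise", "perm_importance"]) < 2 / math.sqrt(n)


class TestLambdaThreshold:
    def test_separable_groups_split_between_extremes(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        clf = fit_lambda_threshold(values, labels)
        assert clf.training_accuracy == 1.0
        assert 3.0 < clf.threshold < 10.0
        assert clf.direction is ThresholdDirection.GREATER_IS_ASD

    def test_direction_learned_from_data(self):
        clf = fit_lambda_threshold(np.array([1.0, 2.0, 10.0, 11.0]), np.array([1, 1, 0, 0]))
        assert clf.direction is ThresholdDirection.LESS_IS_ASD
        assert clf.training_accuracy == 1.0

    def test_accuracy_at_least_majority_prior(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        clf = fit_lambda_threshold(values, labels)
        prior = max(labels.mean(), 1 - labels.mean())
        assert clf.training_accuracy >= prior

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=20)
        labels = (rng.random(20) < 0.5).astype(int)
        clf = fit_lambda_threshold(values, labels)
        best = 0.0
        for thr in np.concatenate([values - 1e-9, values + 1e-9]):
            for direction in (1, -1):
                pred = (values >= thr) if direction == 1 else (values < thr)
                best = max(best, np.mean(pred.astype(int) == labels))
        assert clf.training_accuracy == pytest.approx(best)

    def test_all_identical_values_degenerate_majority(self):
        clf = fit_lambda_threshold(np.full(5, 2.0), np.array([1, 1, 1, 0, 0]))
        assert clf.degenerate
        assert np.all(clf.predict(np.full(5, 2.0)) == 1)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        cm = confusion_metrics(["ASD", "TD", "ASD"], ["ASD", "TD", "ASD"])
        assert cm.accuracy == cm.sensitivity == cm.specificity == cm.precision == 1.0

    def test_hand_counted_table(self):
        cm = confusion_metrics(["ASD", "ASD", "TD", "TD"], ["ASD", "TD", "TD", "TD"])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 2, 0)
        assert cm.accuracy == 0.75
        assert cm.sensitivity == 1.0
        assert cm.specificity == pytest.approx(2 / 3)
        assert cm.precision == 0.5

    def test_undefined_ratio_is_nan_not_zero(self):
        cm = confusion_metrics(["TD", "TD"], ["TD", "TD"])
        assert math.isnan(cm.sensitivity)
        assert cm.specificity == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="length mismatch"):
            confusion_metrics(["ASD"], ["ASD", "TD"])


class _OracleClassifier:
    """Predicts the training majority label; used to test CV mechanics."""

    def __init__(self, truth_col="y"):
        self.truth_col = truth_col

    def fit(self, X, y):
        return self

    def predict(self, X):
        return X[self.truth_col].to_numpy(int)


class _ConstantClassifier:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.ones(len(X), dtype=int)


class TestCrossValidate:
    def _data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = pd.DataFrame({"y": y, "lambda": y * 2.0 + rng.normal(0, 0.5, n)})
        return X, y

    def test_truth_telling_classifier_is_perfect(self):
        X, y = self._data()
        pooled, folds = cross_validate(_OracleClassifier(), X, y, CVConfig(seed=3))
        assert pooled.accuracy == 1.0
        assert len(folds) == 5

    def test_constant_classifier_scores_class_prior(self):
        X, y = self._data()
        pooled, _ = cross_validate(_ConstantClassifier(), X, y, CVConfig(seed=3))
        assert pooled.accuracy == pytest.approx(y.mean())

    def test_pooled_counts_sum_to_n_and_each_trial_once(self):
        X, y = self._data(n=37, seed=5)
        pooled, folds = cross_validate(
            LambdaThresholdClassifier(), X, y, CVConfig(n_folds=5, seed=1)
        )
        assert pooled.n == len(X)
        assert sum(f["n_test"] for f in folds) == len(X)

    def test_pooled_counts_match_fold_recomputation(self):
        X, y = self._data(n=40, seed=7)
        pooled, folds = cross_validate(
            LambdaThresholdClassifier(), X, y, CVConfig(n_folds=5, seed=11)
        )
        # independent recomposition from the per-fold records
        tp = sum(f["tp"] for f in folds)
        fp = sum(f["fp"] for f in folds)
        tn = sum(f["tn"] for f in folds)
        fn = sum(f["fn"] for f in folds)
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (tp, fp, tn, fn)

    def test_participant_grouping_keeps_participants_whole(self):
        rng = np.random.default_rng(2)
        n = 40
        y = np.repeat([0, 1], n // 2)
        participants = np.array([f"p{i // 4}" for i in range(n)])
        X = pd.DataFrame({"lambda": y + rng.normal(0, 0.3, n)})
        cv = CVConfig(n_folds=5, seed=0, grouping=Grouping.BY_PARTICIPANT)

        class Recorder(LambdaThresholdClassifier):
            test_sets = []

            def predict(self, X_):
                Recorder.test_sets.append(X_.index.to_numpy())
                return super().predict(X_)

        cross_validate(Recorder(), X, y, cv, groups=participants)
        fold_of = {}
        for fold_idx, idx in enumerate(Recorder.test_sets):
            for i in idx:
                fold_of[participants[i]] = fold_of.get(participants[i], fold_idx)
                assert fold_of[participants[i]] == fold_idx
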