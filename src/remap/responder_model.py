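"""Multinomial responder-status classifier.

The trial's exploratory model predicts the three-way overall responder
status (non-responder / partial responder / responder) from the
baseline-to-T3 differentials of the rule features (BAS, the five MFI
domains and aggregate, SF-36 RP/VT/SF and PCS). The pipeline is:

1. z-score standardization of features (fit on training data only),
2. multinomial (softmax) logistic regression with an L2 (ridge) penalty,
   L-BFGS solver, up to 1000 iterations,
3. repeated stratified k-fold cross-validation (3 splits x 5 repeats),
4. coefficient summaries: per-class betas with 95% CIs and odds ratios,
5. a two-step refinement: L1 (lasso) feature selection followed by an L2
   refit on the surviving features,
6. application of the refined model to participants who could not be
   stratified by rule (no T3 data).

Coefficients are reported on the standardized scale in scikit-learn's
symmetric (sum-to-zero) softmax parameterization, so each class has one
beta per feature interpretable as "this class vs. the rest"; a
reference-class parameterization is available for conventional Wald
inference. Wald CIs use the observed information of the penalized
(symmetric) or unpenalized (reference) likelihood; a percentile bootstrap
is the fallback when the information matrix is singular, which happens
under quasi-separation — those coefficients are flagged unstable rather
than reported with infinite bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import classification_report, confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler

from .imputation import FeatureTable

#: fixed class order; also the deterministic tie-break order for argmax
CLASS_ORDER = ("non_responder", "partial_responder", "responder")

_Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class ModelConfig:
    penalty: str = "l2"  # "l2" or "l1"
    C: float = 1.0  # inverse regularization strength
    max_iter: int = 1000
    cv_splits: int = 3
    cv_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        if self.cv_splits < 2:
            raise ValueError("cv_splits must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class FittedClassifier:
    classes: tuple[str, ...]
    coef: np.ndarray  # (n_classes, n_features), standardized scale
    intercept: np.ndarray  # (n_classes,)
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: tuple[str, ...]
    config: ModelConfig
    converged: bool = True

    def _standardize(self, table: FeatureTable) -> np.ndarray:
        if tuple(table.data.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: model was trained on {self.feature_names}, "
                f"got {tuple(table.data.columns)}"
            )
        X = table.data.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("feature table contains non-finite values")
        return (X - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        Z = self._standardize(table)
        return softmax(Z @ self.coef.T + self.intercept, axis=1)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "feature_names": list(self.feature_names),
            "config": self.config.__dict__,
            "converged": self.converged,
        }


@dataclass
class CVReport:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    per_class_metrics: dict  # precision/recall/f1/support per class
    confusion: pd.DataFrame  # rows = true class, cols = predicted
    calibration: pd.DataFrame  # class, bin, mean_predicted, observed_freq, n

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "per_class_metrics": self.per_class_metrics,
            "confusion": self.confusion.to_dict(),
        }


def _check_inputs(
    table: FeatureTable, labels: Sequence[str], expected: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = table.data.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match table rows")
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing or non-finite values")
    absent = [c for c in expected if c not in set(y)]
    if absent:
        raise ValueError(f"class(es) absent from labels: {absent}")
    return X, y


def fit_multinomial(
    table: FeatureTable,
    labels: Sequence[str],
    config: ModelConfig = ModelConfig(),
    expected_classes: Sequence[str] = CLASS_ORDER,
) -> FittedClassifier:
    """Standardize and fit the penalized multinomial logistic model."""
    X, y = _check_inputs(table, labels, expected_classes)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    solver = "lbfgs" if config.penalty == "l2" else "saga"
    clf = LogisticRegression(
        penalty=config.penalty, C=config.C, solver=solver,
        max_iter=config.max_iter, random_state=config.seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clf.fit(Z, y)
        if any("onverge" in str(w.message) for w in caught):
            converged = False
            warnings.warn("optimizer hit max_iter without converging", stacklevel=2)
    # store classes in the canonical order so argmax tie-breaking is fixed
    exp = list(expected_classes)
    present = sorted(
        set(y), key=lambda c: (exp.index(c) if c in exp else len(exp), str(c))
    )
    order = np.array([list(clf.classes_).index(c) for c in present])
    classes = tuple(clf.classes_[order])
    return FittedClassifier(
        classes=classes,
        coef=clf.coef_[order],
        intercept=clf.intercept_[order],
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        feature_names=tuple(table.data.columns),
        config=config,
        converged=converged,
    )


def predict_statuses(
    model: FittedClassifier, table: FeatureTable
) -> tuple[list[str], np.ndarray]:
    """Argmax class per row (ties broken by the fixed class order) + probs."""
    proba = model.predict_proba(table)
    # classes are stored in CLASS_ORDER, so argmax's first-max rule is the
    # deterministic tie-break non_responder < partial_responder < responder
    idx = np.argmax(proba, axis=1)
    return [model.classes[i] for i in idx], proba


# ---------------------------------------------------------------------------
# inference


def _softmax_hessian(
    Z: np.ndarray, P: np.ndarray, ridge: float, n_feat: int
) -> np.ndarray:
    """Observed information of the softmax log-likelihood.

    Parameters are ordered class-major: for each class, its feature
    coefficients then its intercept. ``ridge`` adds the L2 penalty curvature
    (1/C) on coefficient entries only.
    """
    n, K = P.shape
    Zb = np.hstack([Z, np.ones((n, 1))])
    p1 = Zb.shape[1]
    H = np.zeros((K * p1, K * p1))
    for k in range(K):
        for l in range(k, K):
            w = P[:, k] * ((k == l) - P[:, l])
            block = Zb.T @ (Zb * w[:, None])
            H[k * p1:(k + 1) * p1, l * p1:(l + 1) * p1] = block
            if l != k:
                H[l * p1:(l + 1) * p1, k * p1:(k + 1) * p1] = block
    if ridge:
        diag = np.zeros(K * p1)
        for k in range(K):
            diag[k * p1:k * p1 + n_feat] = ridge
        H += np.diag(diag)
    return H


def summarize_coefficients(
    model: FittedClassifier,
    table: FeatureTable,
    labels: Sequence[str],
    method: str = "wald",
    seed: int = 0,
    parameterization: str = "symmetric",
    n_boot: int = 2000,
    unstable_width: float = 10.0,
) -> pd.DataFrame:
    """Per class x feature beta, 95% CI, odds ratio, and OR CI.

    ``parameterization='symmetric'`` (default) reports the sum-to-zero
    softmax betas, one per class per feature ("this class vs the rest"),
    with Wald covariance from the ridge-penalized observed information.
    ``'reference'`` drops the first class as reference and uses the
    unpenalized information (standard multinomial-logit Wald inference).
    ``method='bootstrap'`` uses seeded percentile bootstrap CIs instead; it
    is also the automatic fallback when the information matrix is singular.
    OR CIs are exact exponentials of the beta CIs.
    """
    if method not in ("wald", "bootstrap"):
        raise ValueError("method must be 'wald' or 'bootstrap'")
    if parameterization not in ("symmetric", "reference"):
        raise ValueError("parameterization must be 'symmetric' or 'reference'")
    X, y = _check_inputs(table, labels, model.classes)
    Z = (X - model.scaler_mean) / model.scaler_scale
    p = len(model.feature_names)
    K = len(model.classes)

    if parameterization == "symmetric":
        coef, intercept, classes = model.coef, model.intercept, model.classes
    else:
        coef = model.coef[1:] - model.coef[0]
        intercept = model.intercept[1:] - model.intercept[0]
        classes = model.classes[1:]

    if method == "wald":
        try:
            se = _wald_se(model, Z, parameterization, p, K)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular information matrix (likely separation); "
                "falling back to bootstrap CIs",
                stacklevel=2,
            )
            method = "bootstrap"
    if method == "bootstrap":
        se = None
        lo, hi = _bootstrap_ci(model, table, y, parameterization, seed, n_boot)

    rows = []
    for ci, cls in enumerate(classes):
        for fi, feat in enumerate(model.feature_names):
            beta = float(coef[ci, fi])
            if se is not None:
                half = _Z95 * se[ci, fi]
                b_lo, b_hi = beta - half, beta + half
            else:
                b_lo, b_hi = lo[ci, fi], hi[ci, fi]
            rows.append(
                {
                    "class": cls,
                    "feature": feat,
                    "beta": beta,
                    "beta_lo": b_lo,
                    "beta_hi": b_hi,
                    "odds_ratio": float(np.exp(beta)),
                    "or_lo": float(np.exp(b_lo)),
                    "or_hi": float(np.exp(b_hi)),
                    "unstable": bool(
                        not np.isfinite([b_lo, b_hi]).all()
                        or (b_hi - b_lo) > unstable_width
                    ),
                }
            )
    return pd.DataFrame(rows)


def _wald_se(
    model: FittedClassifier, Z: np.ndarray, parameterization: str, p: int, K: int
) -> np.ndarray:
    P = softmax(Z @ model.coef.T + model.intercept, axis=1)
    if parameterization == "symmetric":
        ridge = 1.0 / model.config.C
        H = _softmax_hessian(Z, P, ridge, p)
        cov = np.linalg.inv(H)
        se = np.empty((K, p))
        for k in range(K):
            idx = slice(k * (p + 1), k * (p + 1) + p)
            se[k] = np.sqrt(np.diag(cov[idx, idx]))
        return se
    # reference parameterization: unpenalized information of the K-1 block
    n = Z.shape[0]
    Zb = np.hstack([Z, np.ones((n, 1))])
    p1 = p + 1
    H = np.zeros(((K - 1) * p1, (K - 1) * p1))
    for k in range(1, K):
        for l in range(k, K):
            w = P[:, k] * ((k == l) - P[:, l])
            block = Zb.T @ (Zb * w[:, None])
            H[(k - 1) * p1:k * p1, (l - 1) * p1:l * p1] = block
            if l != k:
                H[(l - 1) * p1:l * p1, (k - 1) * p1:k * p1] = block
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("information matrix is singular")
    cov = np.linalg.inv(H)
    se = np.empty((K - 1, p))
    for k in range(K - 1):
        idx = slice(k * p1, k * p1 + p)
        se[k] = np.sqrt(np.diag(cov[idx, idx]))
    return se


def _bootstrap_ci(
    model: FittedClassifier,
    table: FeatureTable,
    y: np.ndarray,
    parameterization: str,
    seed: int,
    n_boot: int,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(set(yb)) < len(model.classes):
            continue  # resample lost a class; skip
        tb = FeatureTable(table.data.iloc[idx].reset_index(drop=True), dict(table.bounds))
        m = fit_multinomial(tb, yb, model.config, expected_classes=model.classes)
        c = m.coef if parameterization == "symmetric" else m.coef[1:] - m.coef[0]
        draws.append(c)
    stack = np.stack(draws)
    return (
        np.percentile(stack, 2.5, axis=0),
        np.percentile(stack, 97.5, axis=0),
    )


# ---------------------------------------------------------------------------
# cross-validation and feature selection


def cross_validate_repeated(
    table: FeatureTable,
    labels: Sequence[str],
    config: ModelConfig = ModelConfig(),
    calibration_bins: int = 10,
) -> CVReport:
    """Repeated stratified k-fold CV with fold-internal standardization.

    The scaler and model are fit inside each training fold only; metrics are
    computed on the held-out fold, so no information leaks from test to
    train. The confusion matrix, per-class metrics, and calibration bins are
    aggregated over all out-of-fold predictions (each row is predicted once
    per repeat).
    """
    X, y = _check_inputs(table, labels, sorted(set(labels)))
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < config.cv_splits]
    if len(too_small):
        raise ValueError(
            f"class(es) with fewer members than cv_splits={config.cv_splits}: "
            f"{dict(too_small)}"
        )
    present = tuple(c for c in CLASS_ORDER if c in set(y)) or tuple(sorted(set(y)))
    rkf = RepeatedStratifiedKFold(
        n_splits=config.cv_splits, n_repeats=config.cv_repeats,
        random_state=config.seed,
    )
    fold_acc, y_true_all, y_pred_all, proba_all = [], [], [], []
    for train_idx, test_idx in rkf.split(X, y):
        sub = FeatureTable(
            table.data.iloc[train_idx].reset_index(drop=True), dict(table.bounds)
        )
        m = fit_multinomial(sub, y[train_idx], config, expected_classes=present)
        test = FeatureTable(
            table.data.iloc[test_idx].reset_index(drop=True), dict(table.bounds)
        )
        pred, proba = predict_statuses(m, test)
        fold_acc.append(float(np.mean(np.asarray(pred, dtype=object) == y[test_idx])))
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(pred)
        proba_all.append(proba)
    fold_acc = np.asarray(fold_acc)
    report = classification_report(
        y_true_all, y_pred_all, labels=list(present), output_dict=True,
        zero_division=0,
    )
    conf = pd.DataFrame(
        confusion_matrix(y_true_all, y_pred_all, labels=list(present)),
        index=list(present), columns=list(present),
    )
    proba_all = np.vstack(proba_all)
    y_true_arr = np.asarray(y_true_all, dtype=object)
    calib_rows = []
    edges = np.linspace(0.0, 1.0, calibration_bins + 1)
    for ci, cls in enumerate(present):
        is_cls = (y_true_arr == cls).astype(float)
        pk = proba_all[:, ci]
        which = np.clip(np.digitize(pk, edges[1:-1]), 0, calibration_bins - 1)
        for b in range(calibration_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            calib_rows.append(
                {
                    "class": cls,
                    "bin": b,
                    "mean_predicted": float(pk[sel].mean()),
                    "observed_freq": float(is_cls[sel].mean()),
                    "n": int(sel.sum()),
                }
            )
    return CVReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        sd_accuracy=float(fold_acc.std(ddof=1)) if len(fold_acc) > 1 else 0.0,
        per_class_metrics=report,
        confusion=conf,
        calibration=pd.DataFrame(calib_rows),
    )


def select_features_l1(
    table: FeatureTable,
    labels: Sequence[str],
    config: ModelConfig = ModelConfig(),
    threshold: float = 1e-8,
) -> list[str]:
    """L1-penalized fit; features with any nonzero coefficient survive."""
    l1_config = replace(config, penalty="l1")
    model = fit_multinomial(table, labels, l1_config,
                            expected_classes=sorted(set(labels)))
    keep = np.abs(model.coef).max(axis=0) > threshold
    if not keep.any():
        raise ValueError(
            "L1 penalty zeroed every coefficient; decrease the penalty "
            "(increase C) to retain features"
        )
    return [f for f, k in zip(model.feature_names, keep) if k]
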