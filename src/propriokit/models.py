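"""Logistic-regression outcome classifiers and their cross-validated metrics.

Five canonical model configurations predict the binary six-month
impairment label from two-week features:

* **Basic** — age, sex, affected arm;
* **Clinical** — Basic + TLT, BIT, FIM;
* **Imaging** — Basic + VLSM mean Z, lesion volume;
* **Robotic** — Basic + the eight APM parameter z-scores;
* **Augmented** — all of the above.

Each is an unpenalised (maximum-likelihood) logistic regression on
z-standardised features, evaluated with stratified 10-fold cross-validation.
Out-of-fold predicted probabilities are pooled before computing the metric
suite (accuracy, F1 for the impaired class, trapezoidal ROC AUC,
sensitivity, specificity); AIC comes from a single full-data fit, since it
is undefined per fold.  Standardisation parameters are learned inside each
training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.exceptions
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .apm import PARAMETER_NAMES

__all__ = [
    "ROBOTIC_FEATURES",
    "CANONICAL_SPECS",
    "ModelSpec",
    "LogisticFit",
    "ModelResult",
    "canonical_specs",
    "stratified_kfold_indices",
    "fit_logistic",
    "evaluate",
    "auc",
    "single_class_baseline",
    "feature_importance",
    "roc_points",
]

ROBOTIC_FEATURES = tuple(f"z_{name}" for name in PARAMETER_NAMES)
_BASIC = ("age", "sex", "affected_arm")
_CLINICAL = ("tlt", "bit", "fim")
_IMAGING = ("vlsm_mean_z", "lesion_volume")

#: name -> feature tuple for the five canonical configurations.
CANONICAL_SPECS: dict[str, tuple[str, ...]] = {
    "Basic": _BASIC,
    "Clinical": _BASIC + _CLINICAL,
    "Imaging": _BASIC + _IMAGING,
    "Robotic": _BASIC + ROBOTIC_FEATURES,
    "Augmented": _BASIC + _CLINICAL + _IMAGING + ROBOTIC_FEATURES,
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration: name, feature list, regularisation."""

    name: str
    features: tuple[str, ...]
    penalty: str = "none"  # "none" (plain MLE) or "ridge"
    ridge_c: float = 1.0

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in spec")
        if self.penalty not in ("none", "ridge"):
            raise ValueError("penalty must be 'none' or 'ridge'")


def canonical_specs() -> list[ModelSpec]:
    """The five canonical model configurations."""
    return [ModelSpec(name=n, features=f) for n, f in CANONICAL_SPECS.items()]


@dataclass
class LogisticFit:
    """A fitted (standardised-feature) logistic regression."""

    features: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    converged: bool
    log_likelihood: float
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_scale: np.ndarray = field(repr=False, default=None)


@dataclass
class ModelResult:
    """Pooled cross-validated predictions and the metric suite for one spec."""

    spec: ModelSpec
    proba: np.ndarray  # pooled out-of-fold P(impaired)
    predicted: np.ndarray  # pooled out-of-fold classes at threshold 0.5
    labels: np.ndarray
    accuracy: float  # percent
    f1: float
    auc: float
    sensitivity: float  # percent
    specificity: float  # percent
    aic: float
    coefficients: pd.DataFrame  # feature, coefficient (standardised), rank

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) of the pooled out-of-fold predictions."""
        y, yhat = self.labels, self.predicted
        tp = int(np.sum((y == 1) & (yhat == 1)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        tn = int(np.sum((y == 0) & (yhat == 0)))
        fn = int(np.sum((y == 1) & (yhat == 0)))
        return tp, fp, tn, fn


def stratified_kfold_indices(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample)."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class must have at least k={k} members")
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = fold
    return folds


def _make_estimator(spec: ModelSpec) -> LogisticRegression:
    # C = inf turns the l2 penalty off: a plain maximum-likelihood fit
    c = np.inf if spec.penalty == "none" else spec.ridge_c
    return LogisticRegression(C=c, solver="lbfgs", max_iter=5000)


def fit_logistic(features: pd.DataFrame, labels: np.ndarray, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit on z-standardised features.

    Rejects rank-deficient designs (e.g. duplicated columns); warns when
    the optimiser fails to converge, which with unpenalised likelihood
    usually signals (quasi-)separation.
    """
    X = features.loc[:, list(spec.features)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise ValueError(f"design for {spec.name!r} is rank-deficient (collinear features)")
    est = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sklearn.exceptions.ConvergenceWarning)
        est.fit(Xs, y)
    converged = bool(np.all(est.n_iter_ < est.max_iter))
    if not converged:
        warnings.warn(
            f"logistic fit for {spec.name!r} did not converge (possible separation)",
            RuntimeWarning,
            stacklevel=2,
        )
    p = np.clip(est.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return LogisticFit(
        features=spec.features,
        coef=est.coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        converged=converged,
        log_likelihood=loglik,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; ties by the midrank convention)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def single_class_baseline(labels: np.ndarray) -> tuple[float, float]:
    """Accuracies (percent) of the two constant classifiers: (majority, minority)."""
    y = np.asarray(labels, dtype=int)
    p = y.mean()
    hi = max(p, 1 - p) * 100.0
    return hi, 100.0 - hi


def evaluate(
    spec: ModelSpec, table: pd.DataFrame, k: int = 10, seed: int = 0, label_col: str = "impaired_6mo"
) -> ModelResult:
    """Stratified k-fold evaluation of one model configuration.

    Out-of-fold probabilities are pooled across folds; classes use a 0.5
    threshold; AIC = 2(p+1) - 2 logLik from one unpenalised full-data fit
    (p = number of features).  Ridge-penalised specs report NaN AIC since
    the penalised objective is not a likelihood.
    """
    y = table[label_col].to_numpy(dtype=int)
    X = table.loc[:, list(spec.features)]
    folds = stratified_kfold_indices(y, k=k, seed=seed)
    proba = np.empty(len(y))
    for fold in range(k):
        test = folds == fold
        train = ~test
        scaler = StandardScaler().fit(X[train])
        est = _make_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sklearn.exceptions.ConvergenceWarning)
            est.fit(scaler.transform(X[train]), y[train])
        proba[test] = est.predict_proba(scaler.transform(X[test]))[:, 1]
    predicted = (proba >= 0.5).astype(int)

    tp = int(np.sum((y == 1) & (predicted == 1)))
    fp = int(np.sum((y == 0) & (predicted == 1)))
    tn = int(np.sum((y == 0) & (predicted == 0)))
    fn = int(np.sum((y == 1) & (predicted == 0)))
    accuracy = 100.0 * (tp + tn) / len(y)
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = float(f1_score(y, predicted, pos_label=1, zero_division=0))

    full = fit_logistic(table, y, ModelSpec(spec.name, spec.features))  # unpenalised for AIC
    aic = 2.0 * (len(spec.features) + 1) - 2.0 * full.log_likelihood
    if spec.penalty != "none":
        aic = float("nan")
    coef_df = pd.DataFrame({"feature": list(spec.features), "coefficient": full.coef})
    coef_df["rank"] = coef_df["coefficient"].abs().rank(ascending=False, method="first").astype(int)
    coef_df = coef_df.sort_values("rank").reset_index(drop=True)

    return ModelResult(
        spec=spec,
        proba=proba,
        predicted=predicted,
        labels=y,
        accuracy=accuracy,
        f1=f1,
        auc=auc(proba, y),
        sensitivity=sensitivity,
        specificity=specificity,
        aic=aic,
        coefficients=coef_df,
    )


def feature_importance(spec: ModelSpec, table: pd.DataFrame, label_col: str = "impaired_6mo") -> pd.DataFrame:
    """Features ranked by |standardised coefficient| of a full-data fit."""
    fit = fit_logistic(table, table[label_col].to_numpy(dtype=int), spec)
    if not fit.converged:
        warnings.warn("importance from a non-converged fit", RuntimeWarning, stacklevel=2)
    df = pd.DataFrame({"feature": list(spec.features), "coefficient": fit.coef})
    df["rank"] = df["coefficient"].abs().rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


def roc_points(result: ModelResult) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) of the pooled predictions."""
    fpr, tpr, thr = roc_curve(result.labels, result.proba)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
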