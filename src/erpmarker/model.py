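"""Neuromarker classifier: false-positive-rate feature selection + logistic
regression inside stratified k-fold cross-validation.

The classifier predicts the probability of being healthy,

    p = 1 / (1 + exp(-(b0 + b1 x1 + ... + bm xm))),

fitted by maximum likelihood with a weak ridge penalty for stability on
separable data. Feature selection keeps features whose univariate two-sample
F-test p-value is below alpha ("false positive rate" selection), computed on
training rows only. Missing values are imputed by training-fold medians and
features standardized by training mean/SD; both are refit inside every fold,
so no information leaks from held-out subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class LogisticModel:
    """Fitted logistic classifier with its preprocessing constants.

    Coefficients apply to imputed, standardized feature values:
    z_i = (impute(x_i) - mean_i) / sd_i.
    """

    intercept: float
    coef: np.ndarray  # per selected feature, standardized space
    selected_features: list[str]
    imputation_values: np.ndarray  # training medians, per selected feature
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray

    def _design(self, x: pd.DataFrame | dict | pd.Series) -> np.ndarray:
        if isinstance(x, dict):
            x = pd.Series(x)
        if isinstance(x, pd.Series):
            x = x.to_frame().T
        vals = x.reindex(columns=self.selected_features).to_numpy(dtype=float)
        miss = np.isnan(vals)
        if miss.any():
            vals = np.where(miss, np.broadcast_to(self.imputation_values,
                                                  vals.shape), vals)
        return (vals - self.standardize_mean) / self.standardize_sd


def fpr_select(
    table: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> np.ndarray:
    """Boolean mask of features with univariate F-test p-value < alpha.

    Missing values are imputed by the column median of the given (training)
    rows before testing; zero-variance columns are never selected.
    """
    classes = np.unique(labels)
    if len(classes) != 2 or min((labels == c).sum() for c in classes) < 2:
        raise ValueError("FPR selection requires >= 2 subjects per class")
    # all-missing columns become constant zero: never selected
    filled = table.fillna(table.median()).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # constant columns get a NaN p-value and are never selected
        warnings.filterwarnings("ignore", message=".*constant.*")
        _, pvals = f_classif(filled.to_numpy(dtype=float),
                             labels.to_numpy())
    mask = np.nan_to_num(pvals, nan=1.0) < alpha
    if not mask.any():
        logger.warning("FPR selection at alpha=%g kept no features", alpha)
    return mask


def fit_logistic(
    table: pd.DataFrame, labels: pd.Series, ridge_c: float = 100.0
) -> LogisticModel:
    """Maximum-likelihood logistic fit (weak ridge, strength 1/ridge_c).

    `table` must already be restricted to the selected features; imputation
    medians and standardization constants are computed here and stored on the
    model. Set ridge_c very large to approach the unpenalized fit.
    """
    if table.shape[1] < 1:
        raise ValueError("fit_logistic requires at least one feature")
    y = labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("fit_logistic requires both classes present")
    medians = table.median().to_numpy(dtype=float)
    medians = np.nan_to_num(medians, nan=0.0)
    x = table.to_numpy(dtype=float)
    x = np.where(np.isnan(x), np.broadcast_to(medians, x.shape), x)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    clf = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=5000)
    clf.fit(z, y)
    return LogisticModel(
        intercept=float(clf.intercept_[0]),
        coef=clf.coef_[0].astype(float),
        selected_features=list(table.columns),
        imputation_values=medians,
        standardize_mean=mean,
        standardize_sd=sd,
    )


def linear_term(model: LogisticModel, x) -> np.ndarray | float:
    """b0 + sum_i b_i z_i — the weighted sum inside the logistic function."""
    lt = model.intercept + model._design(x) @ model.coef
    return float(lt[0]) if lt.size == 1 else lt


def predict_probability(model: LogisticModel, x) -> np.ndarray | float:
    """Probability of being healthy: the logistic of the linear term."""
    lt = model.intercept + model._design(x) @ model.coef
    p = 1.0 / (1.0 + np.exp(-lt))
    return float(p[0]) if p.size == 1 else p


def feature_importance(model: LogisticModel) -> pd.Series:
    """Absolute coefficients normalized by their sum (intercept excluded)."""
    a = np.abs(model.coef)
    total = a.sum()
    if total == 0:
        raise ValueError("feature importance undefined for all-zero coefficients")
    return pd.Series(a / total, index=model.selected_features,
                     name="importance")


def stratified_folds(
    y: np.ndarray, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-stratified k-fold partition as even as the class sizes allow.

    Each class is shuffled and split into k nearly-equal chunks (sizes
    differing by at most one), so e.g. 30 controls + 20 patients under k=10
    hold out exactly 3 + 2 per fold, and 19 patients yield nine folds of 2
    and one of 1. Unlike scikit-learn's StratifiedKFold, k may exceed the
    smaller class size (some folds then hold out no member of that class).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    test_sets: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for fold, chunk in enumerate(np.array_split(idx, k)):
            test_sets[fold].extend(chunk.tolist())
    all_idx = np.arange(len(y))
    out = []
    for test in test_sets:
        test_arr = np.sort(np.asarray(test, dtype=int))
        train = np.setdiff1d(all_idx, test_arr)
        out.append((train, test_arr))
    return out


@dataclass
class CVResult:
    """Pooled out-of-fold scores plus per-fold models."""

    scores: pd.Series  # per subject, probability of being healthy
    fold_assignment: pd.Series
    fold_models: list[LogisticModel] = field(default_factory=list)


def cross_validate(
    table: pd.DataFrame,
    labels: pd.Series,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    ridge_c: float = 100.0,
) -> CVResult:
    """Stratified k-fold protocol: select, impute, standardize and fit on the
    training rows of each fold; score the held-out rows once each.

    A fold whose selection is empty falls back to an intercept-only score
    (the training base rate), logged as such.
    """
    y = labels.to_numpy()
    scores = pd.Series(index=table.index, dtype=float, name="score")
    folds = pd.Series(index=table.index, dtype=int, name="fold")
    models: list[LogisticModel] = []
    for fold, (train, test) in enumerate(stratified_folds(y, k, seed)):
        y_train = labels.iloc[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {fold}: training rows contain one class")
        mask = fpr_select(table.iloc[train], y_train, alpha)
        if mask.any():
            cols = table.columns[mask]
            model = fit_logistic(table.iloc[train][cols], y_train, ridge_c)
            scores.iloc[test] = predict_probability(model, table.iloc[test])
        else:
            logger.warning("fold %d: empty selection, intercept-only score", fold)
            model = None
            scores.iloc[test] = float(y_train.mean())
        folds.iloc[test] = fold
        if model is not None:
            models.append(model)
    return CVResult(scores=scores, fold_assignment=folds, fold_models=models)


def train_final_model(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    ridge_c: float = 100.0,
) -> LogisticModel:
    """Rerun selection and fit on the full training table (the final model)."""
    mask = fpr_select(table, labels, alpha)
    if not mask.any():
        raise ValueError("final model: FPR selection kept no features")
    return fit_logistic(table[table.columns[mask]], labels, ridge_c)
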