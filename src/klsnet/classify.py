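"""Pairwise subtype classification with leak-free nested cross-validation.

Per outer fold: train-only covariate residualization, train-parameter
min-max scaling, L1-logistic feature selection with an inner stratified CV,
then an L2-logistic refit on the selected features whose penalty is also
tuned in the inner loop. Held-out probabilities are pooled across outer
folds into a single ROC; significance comes from a label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

#: default L1/L2 penalty grid (inverse regularization strength C)
DEFAULT_PENALTY_GRID = tuple(np.logspace(-3, 3, 20))

#: permutation iterations at full scale
DEFAULT_N_PERMUTATIONS = 5000


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with binary class labels."""

    subject_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if v.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if (y == 0).sum() < 2 or (y == 1).sum() < 2:
            raise ValueError("need >= 2 subjects per class")
        self.subject_ids = tuple(self.subject_ids)
        self.feature_ids = tuple(self.feature_ids)
        self.values = v
        self.labels = y

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            tuple(np.asarray(self.subject_ids)[idx]),
            self.feature_ids,
            self.values[idx],
            self.labels[idx],
        )


@dataclass
class ClassificationReport:
    task: str
    subject_ids: tuple[str, ...]
    pooled_scores: np.ndarray
    labels: np.ndarray
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    permutation_p: float = float("nan")
    n_permutations: int = 0
    selected_features: list[list[str]] = field(default_factory=list)
    selection_frequency: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    degenerate: bool = False


def residualize_features(
    train: np.ndarray,
    test: np.ndarray,
    cov_train: np.ndarray,
    cov_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature linear covariate model fitted on the training partition
    only; train-fitted coefficients applied to both partitions."""
    cov_train = np.asarray(cov_train, dtype=float)
    cov_test = np.asarray(cov_test, dtype=float)
    # train-constant columns are absorbed by the intercept; dropping them is
    # a train-only decision, so no leakage
    varying = cov_train.std(axis=0) > 0
    cov_train = cov_train[:, varying]
    cov_test = cov_test[:, varying]
    x = np.column_stack([np.ones(len(cov_train)), cov_train])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(x, np.asarray(train, dtype=float), rcond=None)
    xt = np.column_stack([np.ones(len(cov_test)), cov_test])
    return train - x @ beta, test - xt @ beta


def minmax_scale(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each feature to [0,1] by the train min/max; test values are
    transformed with the same parameters and may fall outside [0,1].

    Returns (train_scaled, test_scaled, kept_column_mask); zero-range train
    features are dropped with a warning.
    """
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    rng = hi - lo
    keep = rng > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-range feature(s)")
    tr = (train[:, keep] - lo[keep]) / rng[keep]
    te = (test[:, keep] - lo[keep]) / rng[keep]
    return tr, te, keep


def _inner_cv_auc(
    x: np.ndarray,
    y: np.ndarray,
    penalty: str,
    c_value: float,
    inner_folds: int,
    seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(x, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        clf = LogisticRegression(
            penalty=penalty, C=c_value, solver="liblinear", max_iter=2000,
            random_state=seed,
        )
        clf.fit(x[tr], y[tr])
        scores = clf.decision_function(x[te])
        aucs.append(_rank_auc(y[te], scores))
    return float(np.mean(aucs)) if aucs else 0.5


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        return 0.5
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def lasso_select(
    x: np.ndarray,
    y: np.ndarray,
    feature_ids: tuple[str, ...],
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """L1-logistic selection: penalty chosen by inner stratified CV mean
    AUC; returns features with non-zero coefficients (possibly empty)."""
    if min((y == 0).sum(), (y == 1).sum()) < inner_folds:
        raise ValueError("too few subjects per class for the inner folds")
    best_c, best_auc = None, -np.inf
    for c in penalty_grid:
        auc = _inner_cv_auc(x, y, "l1", c, inner_folds, seed)
        if auc > best_auc:
            best_auc, best_c = auc, c
    clf = LogisticRegression(
        penalty="l1", C=best_c, solver="liblinear", max_iter=2000, random_state=seed
    )
    clf.fit(x, y)
    nz = np.flatnonzero(np.abs(clf.coef_[0]) > 0)
    return [feature_ids[j] for j in nz]


def nested_cv_classify(
    features: FeatureMatrix,
    covariates: pd.DataFrame,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    task: str = "",
) -> ClassificationReport:
    """Leak-free nested stratified CV; pooled out-of-fold probabilities."""
    y = features.labels
    if min((y == 0).sum(), (y == 1).sum()) < outer_folds:
        raise ValueError(
            "class counts smaller than the outer fold count; use fewer folds"
        )
    cov = covariates.loc[list(features.subject_ids)].to_numpy(dtype=float)
    x_all = features.values
    pooled = np.full(len(y), np.nan)
    selections: list[list[str]] = []
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(outer.split(x_all, y)):
        fold_seed = seed + 1000 * (fold + 1)
        xtr_r, xte_r = residualize_features(x_all[tr], x_all[te], cov[tr], cov[te])
        xtr, xte, keep = minmax_scale(xtr_r, xte_r)
        kept_ids = tuple(np.asarray(features.feature_ids)[keep])
        selected = lasso_select(
            xtr, y[tr], kept_ids, penalty_grid, inner_folds, fold_seed
        )
        if not selected:
            warnings.warn("LASSO selected no features; falling back to all")
            selected = list(kept_ids)
        sel_idx = [kept_ids.index(f) for f in selected]
        xtr_s, xte_s = xtr[:, sel_idx], xte[:, sel_idx]
        best_c, best_auc = None, -np.inf
        for c in penalty_grid:
            auc = _inner_cv_auc(xtr_s, y[tr], "l2", c, inner_folds, fold_seed)
            if auc > best_auc:
                best_auc, best_c = auc, c
        clf = LogisticRegression(
            penalty="l2", C=best_c, solver="liblinear", max_iter=2000,
            random_state=fold_seed,
        )
        clf.fit(xtr_s, y[tr])
        pooled[te] = clf.predict_proba(xte_s)[:, 1]
        selections.append(list(selected))
    assert not np.isnan(pooled).any(), "every subject must be predicted once"
    auc, acc, sens, spec, thr, degen = pooled_roc_youden(pooled, y)
    freq: dict[str, float] = {}
    for sel in selections:
        for f in sel:
            freq[f] = freq.get(f, 0.0) + 1.0 / outer_folds
    return ClassificationReport(
        task=task,
        subject_ids=features.subject_ids,
        pooled_scores=pooled,
        labels=y,
        auc=auc,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
        selected_features=selections,
        selection_frequency=freq,
        seed=seed,
        degenerate=degen,
    )


def pooled_roc_youden(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, float, bool]:
    """(auc, accuracy, sensitivity, specificity, threshold, degenerate) at
    the Youden-optimal operating point (ties -> lowest threshold)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(s) == 0:
        k = int((y == 1).sum())
        return 0.5, max(k, len(y) - k) / len(y), float(k > 0), float(k == 0), float(s[0]), True
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    thr = float(thresholds[best])
    pred = (s >= thr).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / (y == 1).sum()
    spec = tn / (y == 0).sum()
    acc = (tp + tn) / len(y)
    return auc, float(acc), float(sens), float(spec), thr, False


def permutation_test_auc(
    features: FeatureMatrix,
    covariates: pd.DataFrame,
    observed_auc: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    **cv_kwargs,
) -> float:
    """p = (1 + #{permuted AUC >= observed}) / (B + 1), rerunning the full
    nested CV on each label permutation."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(features.labels))
        fm = FeatureMatrix(
            features.subject_ids, features.feature_ids,
            features.values, features.labels[perm],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = nested_cv_classify(fm, covariates, seed=seed, **cv_kwargs)
        if rep.auc >= observed_auc:
            count += 1
    return (1 + count) / (n_permutations + 1)
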