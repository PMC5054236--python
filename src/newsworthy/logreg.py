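"""Regularized logistic regression with nested cross-validated AUC.

The classifier minimizes

    1/2 ||w||^2  +  lambda * sum_i log(1 + exp(-y_i (w'X_i + w0)))

with y_i in {-1, +1} and an unpenalized intercept, so *smaller* lambda
means *stronger* regularization (lambda plays the role of the C parameter
in LIBLINEAR/scikit-learn solvers).
Performance is summarized by the AUC — the probability that a random
positive article is scored above a random negative one — estimated by
stratified five-fold cross-validation with the regularization strength
selected independently inside each training split (nested CV over a
logarithmic grid from 1e-5 to 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("newsworthy")

#: logarithmic line-search grid for lambda: powers of ten, 1e-5 .. 1e2
DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-5, 3))


@dataclass
class LogRegModel:
    """Fitted weights of the regularized logistic model."""

    w: np.ndarray
    w0: float
    lam: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.w0):
            raise ValueError("non-finite model weights")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class CVResult:
    """Per-fold AUCs from nested cross-validation."""

    fold_aucs: list[float]
    selected_lambdas: list[float]
    seed: int
    fold_assignments: np.ndarray = field(repr=False, default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "selected_lambdas": [float(l) for l in self.selected_lambdas],
            "seed": self.seed,
        }


def _validate_Xy(X, y) -> tuple:
    y = np.asarray(y).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present in y")
    if sp.issparse(X):
        if not np.all(np.isfinite(X.data)):
            raise ValueError("non-finite entries in X")
    elif not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    return X, y


def fit_logreg(X, y, lam: float, tol: float = 1e-9, max_iter: int = 10_000) -> LogRegModel:
    """Fit the penalized logistic objective at a fixed regularization strength.

    ``lam`` multiplies the data-fit (log-loss) term, so lam -> 0 shrinks all
    weights to zero.  The intercept is never penalized.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    X, y = _validate_Xy(X, y)
    clf = LogisticRegression(C=lam, solver="lbfgs", tol=tol, max_iter=max_iter)
    clf.fit(X, y)
    return LogRegModel(w=clf.coef_[0], w0=float(clf.intercept_[0]), lam=lam)


def predict_scores(model: LogRegModel, X) -> np.ndarray:
    """Linear scores w'X_i + w0 (rank-equivalent to class probabilities)."""
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but model has {model.w.shape[0]} weights")
    return np.asarray(X @ model.w).ravel() + model.w0


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals (#concordant positive-negative pairs + 1/2 #ties) / (n_pos * n_neg);
    ties receive half credit.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == np.max(labels)
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0 or np.unique(labels).size != 2:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks give half credit to ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _select_lambda(X, y, lambda_grid, k_inner: int, seed: int, tol: float) -> float:
    """Inner-CV lambda selection: maximize mean inner-fold AUC.

    Ties go to the smaller lambda (stronger regularization).  Selection
    fits use a looser optimizer tolerance than the final refits: AUC is a
    rank statistic and is insensitive to the last digits of the weights.
    """
    inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    grid = sorted(lambda_grid)
    mean_aucs = np.zeros(len(grid))
    sel_tol = max(tol, 1e-4)
    for tr, te in inner.split(np.zeros(len(y)), y):
        for g, lam in enumerate(grid):
            m = fit_logreg(X[tr], y[tr], lam, tol=sel_tol)
            mean_aucs[g] += auc(predict_scores(m, X[te]), y[te])
    return grid[int(np.argmax(mean_aucs))]


def cross_validate(
    X,
    y,
    k: int = 5,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    tol: float = 1e-6,
) -> CVResult:
    """Nested, stratified k-fold cross-validated AUC.

    The data are split into k stratified folds.  For each outer fold the
    regularization strength is chosen by (k-1)-fold cross-validation on the
    training folds only, the model is refit on all training folds at the
    chosen lambda, and AUC is measured on the held-out fold.  The outer
    test fold is never touched during selection.
    """
    X, y = _validate_Xy(X, y)
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    if min(np.bincount((y == np.max(y)).astype(int))) < k:
        raise ValueError(f"each class needs at least k={k} members")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignments = np.full(len(y), -1, dtype=int)
    fold_aucs, selected = [], []
    for fold, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y)):
        fold_assignments[te] = fold
        lam = _select_lambda(X[tr], y[tr], lambda_grid, k_inner=k - 1, seed=child_seeds[fold], tol=tol)
        model = fit_logreg(X[tr], y[tr], lam, tol=tol)
        fold_aucs.append(auc(predict_scores(model, X[te]), y[te]))
        selected.append(lam)
        logger.info("fold %d: lambda=%g AUC=%.4f", fold, lam, fold_aucs[-1])
    return CVResult(fold_aucs=fold_aucs, selected_lambdas=selected, seed=seed,
                    fold_assignments=fold_assignments)
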