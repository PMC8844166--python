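"""Voxel-wise sparse linear classification of hemisphere side.

A LASSO "classifier": L1-penalized least squares on side labels encoded
-1/+1, with class assignment by the sign of the linear score. The penalty
is chosen per training fold by inner cross-validated accuracy under the
one-standard-error rule (the sparsest model statistically tied with the
best), so noise-only data collapses to the empty model. An L1-regularized logistic variant is
selectable. The final weight map is refit on all rows at the penalty chosen
by inner validation on the full data, and devectorized to a signed 3-D map
whose nonzero voxels are the classifier-relevant features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.model_selection import StratifiedKFold

from .lowdim import CVReport, cv_splits
from .prep import DataMatrix, devectorize
from .volume_io import BrainVolume

__all__ = ["SparseFitResult", "lasso_cv", "lasso_penalty_grid"]


@dataclass
class SparseFitResult:
    report: CVReport
    weight_map: BrainVolume     # signed refit weights on the grid
    weights: np.ndarray         # length-V refit weight vector
    n_nonzero: int
    penalty: float              # penalty of the final refit
    fold_penalties: np.ndarray  # penalty chosen in each outer fold


def lasso_penalty_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 50,
                       decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty grid from the smallest alpha that zeroes all
    weights down by ``decades`` decades (descending)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.abs(Xc.T @ yc).max() / n
    if alpha_max <= 0:
        raise ValueError("all features are constant: nothing to fit")
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades,
                       n_alphas)


def _path_coefs(X, y, alphas):
    """Lasso coefficient path plus intercepts over a fixed (descending)
    alpha grid; returns (coefs (V, A), intercepts (A,))."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    _, coefs, _ = lasso_path(X - x_mean, y - y_mean, alphas=alphas)
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts


def _one_se_pick(acc: np.ndarray, alphas: np.ndarray) -> float:
    """One-standard-error rule on inner accuracies (rows = folds): the
    largest penalty whose mean accuracy is within one SE of the best.
    Collapses to the plain argmax when folds agree exactly; on pure-noise
    data it collapses to the sparsest (all-zero) end of the path."""
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(acc.shape[0])
    best = int(np.argmax(mean))
    ok = np.flatnonzero(mean >= mean[best] - se[best])
    return float(alphas[ok[0]])   # alphas descending: first = largest


def _inner_select(X, y, alphas, seed, inner_folds=3):
    """Penalty chosen by inner cross-validated accuracy (1-SE rule)."""
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    acc = []
    for tr, va in cv.split(X, y):
        coefs, intercepts = _path_coefs(X[tr], y[tr], alphas)
        scores = X[va] @ coefs + intercepts
        pred = np.where(scores >= 0, 1, -1)
        acc.append((pred == y[va][:, None]).mean(axis=0))
    return _one_se_pick(np.asarray(acc), alphas)


def lasso_cv(data: DataMatrix, folds: int = 3, repetitions: int = 1,
             seed: int = 0, n_alphas: int = 50,
             model: str = "lasso",
             alphas: Optional[np.ndarray] = None,
             group_by_subject: bool = False) -> SparseFitResult:
    """Cross-validated sparse classification of hemisphere side.

    Parameters
    ----------
    model : ``"lasso"`` (L1 least squares on +-1 labels, default) or
        ``"logistic"`` (L1-penalized logistic regression).
    group_by_subject : keep both hemispheres of a subject in the same fold
        (leakage-safe); off by default, matching the common tooling default.
    """
    X = data.X
    y = data.side_targets().astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("all features are constant")
    if alphas is None:
        alphas = lasso_penalty_grid(X, y, n_alphas=n_alphas)
    alphas = np.asarray(alphas, dtype=float)

    groups = data.subject_ids if group_by_subject else None
    accs, prec_l, prec_r, fold_pen = [], [], [], []
    for i, (tr, te) in enumerate(cv_splits(X, y, folds, repetitions, seed,
                                           groups)):
        if model == "logistic":
            alpha = _inner_select_logistic(X[tr], y[tr], alphas, seed + i)
            w, b = _fit_logistic(X[tr], y[tr], alpha)
        else:
            alpha = _inner_select(X[tr], y[tr], alphas, seed + i)
            w, b = _fit_lasso(X[tr], y[tr], alpha)
        pred = np.where(X[te] @ w + b >= 0, 1, -1)
        accs.append(float(np.mean(pred == y[te])))
        tp_r = np.sum((pred == 1) & (y[te] == 1))
        tp_l = np.sum((pred == -1) & (y[te] == -1))
        n_pred_r = np.sum(pred == 1)
        n_pred_l = np.sum(pred == -1)
        prec_r.append(tp_r / n_pred_r if n_pred_r else np.nan)
        prec_l.append(tp_l / n_pred_l if n_pred_l else np.nan)
        fold_pen.append(alpha)

    # final penalty: median (log scale) of the per-fold selections, a more
    # stable summary than one further selection pass on all rows
    alpha_final = float(np.exp(np.median(np.log(fold_pen))))
    if model == "logistic":
        w, _ = _fit_logistic(X, y, alpha_final)
    else:
        w, _ = _fit_lasso(X, y, alpha_final)

    accs = np.asarray(accs)
    report = CVReport(
        fold_accuracies=accs,
        precision_left=np.asarray(prec_l),
        precision_right=np.asarray(prec_r),
        mean_accuracy=float(accs.mean()),
        min_accuracy=float(accs.min()),
        max_accuracy=float(accs.max()),
        scheme={"folds": folds, "repetitions": repetitions, "seed": seed,
                "grouping": "subject" if group_by_subject else "none",
                "model": model},
    )
    weight_map = devectorize(w, data.voxel_index, data.grid_shape, data.affine)
    return SparseFitResult(
        report=report, weight_map=weight_map, weights=w,
        n_nonzero=int(np.count_nonzero(w)), penalty=float(alpha_final),
        fold_penalties=np.asarray(fold_pen),
    )


def _fit_lasso(X, y, alpha):
    coefs, intercepts = _path_coefs(X, y, np.asarray([alpha]))
    return coefs[:, 0], float(intercepts[0])


def _fit_logistic(X, y, alpha):
    # sklearn's C is the inverse penalty strength
    clf = LogisticRegression(penalty="l1", C=1.0 / (alpha * X.shape[0]),
                             solver="liblinear")
    clf.fit(X, (y > 0).astype(int))
    return clf.coef_[0], float(clf.intercept_[0])


def _inner_select_logistic(X, y, alphas, seed, inner_folds=3):
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    acc = []
    for tr, va in cv.split(X, y):
        fold = []
        for a in alphas:
            w, b = _fit_logistic(X[tr], y[tr], a)
            pred = np.where(X[va] @ w + b >= 0, 1, -1)
            fold.append(np.mean(pred == y[va]))
        acc.append(fold)
    return _one_se_pick(np.asarray(acc), alphas)
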