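"""Low-dimensional hemisphere classification: UMAP embedding + linear SVM.

All hemispheres (left and right rows of the data matrix) are embedded
jointly into two dimensions; a linear support vector machine is then
cross-validated on the 2-D coordinates with side as the target. Embedding
spread per side is compared with a variance-ratio F-test, and
cross-validation score sets are compared with an independent two-sample
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import precision_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedGroupKFold
from sklearn.svm import SVC

from .prep import DataMatrix

__all__ = [
    "EmbeddingParams",
    "EmbeddingResult",
    "CVReport",
    "embed_2d",
    "svm_cv",
    "variance_ftest",
    "compare_score_sets",
]


@dataclass
class EmbeddingParams:
    """UMAP hyperparameters (unitless; exposed because no canonical values
    exist for this application)."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    n_components: int = 2


@dataclass
class EmbeddingResult:
    coords: np.ndarray          # (N, 2), row order of the DataMatrix
    side_labels: np.ndarray     # (N,)
    method_params: dict


@dataclass
class CVReport:
    """Per-fold accuracies and per-class precisions of a repeated CV run."""

    fold_accuracies: np.ndarray
    precision_left: np.ndarray
    precision_right: np.ndarray
    mean_accuracy: float
    min_accuracy: float
    max_accuracy: float
    scheme: dict = field(default_factory=dict)


def embed_2d(data: DataMatrix,
             params: Optional[EmbeddingParams] = None,
             seed: int = 0) -> EmbeddingResult:
    """Jointly embed all hemisphere rows into 2-D with UMAP.

    Deterministic for fixed (data, params, seed): the reducer runs
    single-threaded with a fixed random state.
    """
    import umap  # deferred: numba compilation on import is slow

    if params is None:
        params = EmbeddingParams()
    N = data.X.shape[0]
    if N < 10:
        raise ValueError(f"need at least 10 rows to embed, got {N}")
    reducer = umap.UMAP(
        n_neighbors=min(params.n_neighbors, N - 1),
        min_dist=params.min_dist,
        metric=params.metric,
        n_components=params.n_components,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(data.X)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=np.float64),
        side_labels=data.side_labels.copy(),
        method_params={
            "n_neighbors": params.n_neighbors, "min_dist": params.min_dist,
            "metric": params.metric, "seed": seed,
        },
    )


def cv_splits(X, y, folds, repetitions, seed, groups=None):
    """Repeated stratified splits; when ``groups`` is given, folds respect
    the grouping (both hemispheres of a subject land in the same fold)."""
    if groups is None:
        cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repetitions,
                                     random_state=seed)
        yield from cv.split(X, y)
    else:
        for rep in range(repetitions):
            cv = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                      random_state=seed + rep)
            yield from cv.split(X, y, groups=groups)


def svm_cv(emb: EmbeddingResult, folds: int = 5, repetitions: int = 5,
           seed: int = 0, C: float = 1.0,
           groups: Optional[np.ndarray] = None) -> CVReport:
    """Repeated stratified k-fold CV of a linear SVM on the embedding.

    Records per-fold accuracy and per-class precision
    (precision of class c = TP_c / (TP_c + FP_c); NaN when a fold predicts
    no member of c, ignored by the summary statistics). Folds are
    stratified by side and, by default, *not* grouped by subject (matching
    the common tooling default); pass ``groups=subject_ids`` for
    leakage-safe subject grouping.
    """
    X, y = emb.coords, emb.side_labels
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    accs, prec_l, prec_r = [], [], []
    for train, test in cv_splits(X, y, folds, repetitions, seed, groups):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("a CV fold lost one of the two classes")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec_l.append(precision_score(y[test], pred, pos_label="left",
                                          zero_division=np.nan))
            prec_r.append(precision_score(y[test], pred, pos_label="right",
                                          zero_division=np.nan))
    accs = np.asarray(accs)
    return CVReport(
        fold_accuracies=accs,
        precision_left=np.asarray(prec_l),
        precision_right=np.asarray(prec_r),
        mean_accuracy=float(accs.mean()),
        min_accuracy=float(accs.min()),
        max_accuracy=float(accs.max()),
        scheme={"folds": folds, "repetitions": repetitions, "seed": seed,
                "grouping": "none" if groups is None else "subject"},
    )


def variance_ftest(emb: EmbeddingResult, dimension: int = 1):
    """Variance-ratio F-test between right and left embedding coordinates.

    F = var(right) / var(left) along the chosen dimension (1 or 2), with the
    two-sided p-value from the F distribution at (n_R - 1, n_L - 1) df.
    """
    if dimension not in (1, 2):
        raise ValueError("dimension must be 1 or 2")
    col = emb.coords[:, dimension - 1]
    r = col[emb.side_labels == "right"]
    l = col[emb.side_labels == "left"]
    if len(r) < 2 or len(l) < 2:
        raise ValueError("need at least 2 points per side")
    var_l = l.var(ddof=1)
    if var_l == 0:
        raise ValueError("zero variance in the left (denominator) coordinates")
    F = r.var(ddof=1) / var_l
    dist = stats.f(len(r) - 1, len(l) - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(p, 1.0))


def compare_score_sets(a, b):
    """Two-sided independent two-sample t-test (pooled variance) between two
    sets of cross-validation fold scores; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each score set needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both score sets are degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
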