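"""All-relevant feature selection by iterated shadow-feature comparison.

Each iteration appends a freshly shuffled ("shadow") copy of every feature
still in play, fits a random forest on the side labels, and scores a "hit"
for every undecided real feature whose importance (mean decrease in
impurity) exceeds the maximum shadow importance. From iteration 5 onward,
hit counts are tested two-sidedly against Binomial(n_iterations, 0.5) with
Bonferroni correction over the features still under test: counts
significantly above chance confirm a feature, counts significantly below
reject it (rejected features leave the model). Features undecided at the
iteration cap remain tentative and are excluded from the selection mask by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .prep import DataMatrix, devectorize
from .volume_io import BrainVolume

__all__ = ["BorutaResult", "boruta"]

CONFIRMED, REJECTED, TENTATIVE = "confirmed", "rejected", "tentative"


@dataclass
class BorutaResult:
    """Per-voxel decisions and provenance of a Boruta run."""

    decisions: np.ndarray        # (V,) of {confirmed, rejected, tentative}
    hit_counts: np.ndarray       # (V,) int, hits while the feature was active
    n_iterations_run: int
    selection_mask: BrainVolume  # binary 3-D, confirmed voxels = 1
    alpha: float
    seed: int
    importance_margin: np.ndarray = field(default=None)  # median imp - shadow max

    @property
    def confirmed(self) -> np.ndarray:
        return self.decisions == CONFIRMED

    def counts(self) -> dict:
        return {k: int((self.decisions == k).sum())
                for k in (CONFIRMED, REJECTED, TENTATIVE)}


def _two_sided_binom_p(hits: np.ndarray, n: int) -> np.ndarray:
    """2 * min(P(X >= hits), P(X <= hits)) for X ~ Binomial(n, 1/2)."""
    p_hi = stats.binom.sf(hits - 1, n, 0.5)
    p_lo = stats.binom.cdf(hits, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))


def boruta(data: DataMatrix, max_iter: int = 100, alpha: float = 0.01,
           seed: int = 0, n_trees: int = 200,
           resolve_tentative: bool = False,
           prescreen: Optional[np.ndarray] = None) -> BorutaResult:
    """All-relevant selection of side-discriminating voxels.

    Parameters
    ----------
    data : DataMatrix with both left and right rows.
    max_iter : iteration cap (must allow the warm-up of 5 iterations).
    alpha : two-sided significance level of the binomial decision test,
        Bonferroni-corrected over the features still under test.
    n_trees : forest size per iteration; importances are mean decrease in
        impurity from depth-unlimited trees.
    resolve_tentative : if True, tentative features whose median importance
        over their active iterations beat the median shadow maximum are
        promoted into the selection mask.
    prescreen : optional boolean length-V mask restricting the candidate
        set (e.g. a dilated union of sparse-classifier supports) to bound
        runtime on very large V; non-candidates are marked rejected.

    Stops early once no feature remains undecided. Identical (data, seed)
    give identical decisions.
    """
    if max_iter < 5:
        raise ValueError("max_iter must be at least 5")
    X = data.X
    y = data.side_targets()
    if len(np.unique(y)) != 2:
        raise ValueError("side labels must contain exactly two classes")
    V = X.shape[1]
    if V < 2:
        raise ValueError("need at least 2 features")

    rng = np.random.default_rng(seed)
    decisions = np.full(V, TENTATIVE, dtype=object)
    if prescreen is not None:
        decisions[~np.asarray(prescreen, dtype=bool)] = REJECTED
    hits = np.zeros(V, dtype=int)
    active = decisions == TENTATIVE       # undecided, still tested
    in_model = active.copy()              # undecided + confirmed stay in the fit
    imp_history = [[] for _ in range(V)]
    shadow_max_history = []

    n_run = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(in_model)
        if idx.size == 0:
            break
        Xa = X[:, idx]
        shadows = Xa.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        Z = np.hstack([Xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
            n_jobs=1)
        rf.fit(Z, y)
        imp = rf.feature_importances_
        real_imp = imp[: idx.size]
        shadow_top = imp[idx.size:].max()
        shadow_max_history.append(shadow_top)
        for pos, j in enumerate(idx):
            imp_history[j].append(real_imp[pos])
        tested = active[idx]
        hits[idx[tested]] += (real_imp[tested] > shadow_top).astype(int)
        n_run = it

        if it >= 5:
            test_idx = np.flatnonzero(active)
            if test_idx.size:
                p = _two_sided_binom_p(hits[test_idx], it)
                sig = p * test_idx.size < alpha
                above = hits[test_idx] > it / 2
                conf = test_idx[sig & above]
                rej = test_idx[sig & ~above]
                decisions[conf] = CONFIRMED
                decisions[rej] = REJECTED
                active[conf] = False
                active[rej] = False
                in_model[rej] = False
        if not active.any():
            break

    selected = decisions == CONFIRMED
    margin = np.full(V, np.nan)
    med_shadow = np.median(shadow_max_history) if shadow_max_history else np.nan
    for j in range(V):
        if imp_history[j]:
            margin[j] = np.median(imp_history[j]) - med_shadow
    if resolve_tentative:
        promote = (decisions == TENTATIVE) & (margin > 0)
        selected = selected | promote

    mask_vol = devectorize(selected.astype(float), data.voxel_index,
                           data.grid_shape, data.affine)
    mask_vol.values = mask_vol.values.astype(np.uint8)
    return BorutaResult(
        decisions=decisions.astype(str), hit_counts=hits,
        n_iterations_run=n_run, selection_mask=mask_vol, alpha=alpha,
        seed=seed, importance_margin=margin,
    )
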