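"""Subgroup reruns of the classification arms and cross-group map overlap.

Splits the data matrix by sex or handedness (handedness binarized into
right vs non-right, pooling left-handed and ambidextrous participants),
reruns the low- and high-dimensional classification plus Boruta selection
per group with identical settings, and quantifies the overlap of the
groups' Boruta masks with the Dice similarity coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .boruta import boruta, BorutaResult
from .compare import dsc
from .highdim import lasso_cv, SparseFitResult
from .lowdim import CVReport, embed_2d, svm_cv, EmbeddingParams
from .prep import DataMatrix

__all__ = ["split_by", "subgroup_pipeline", "SubgroupReport"]

logger = logging.getLogger(__name__)

MIN_GROUP_SUBJECTS = 5
_MISSING = {"", "n/a", "na", "nan", "unknown", "none"}


@dataclass
class SubgroupReport:
    label: str
    n_subjects: int
    lowdim: Optional[CVReport]
    sparse: Optional[SparseFitResult]
    boruta: Optional[BorutaResult]


def split_by(data: DataMatrix, column: str) -> List[Tuple[str, DataMatrix]]:
    """Split a DataMatrix into subgroup matrices by a participants column.

    Both hemispheres of a subject stay together. Subjects with missing or
    "unknown" values are excluded (count logged). Handedness is binarized
    right vs non-right. Groups with fewer than 5 subjects raise an error.
    """
    if column not in ("sex", "handedness"):
        raise ValueError("column must be 'sex' or 'handedness'")
    if data.groups is None or column not in data.groups.columns:
        raise ValueError(f"participants column {column!r} not available")
    col = data.groups[column].astype(str)
    valid = ~col.str.lower().isin(_MISSING) & col.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("split_by(%s): excluded %d subjects with missing values",
                    column, n_dropped)
    col = col[valid]
    if column == "handedness":
        col = col.where(col == "right", "non-right")
    out = []
    for label in sorted(col.unique()):
        ids = col.index[col == label]
        if len(ids) < MIN_GROUP_SUBJECTS:
            raise ValueError(
                f"group {label!r} has only {len(ids)} subjects; at least "
                f"{MIN_GROUP_SUBJECTS} are required"
            )
        out.append((label, data.rows_for(ids)))
    return out


def subgroup_pipeline(groups: List[Tuple[str, DataMatrix]],
                      seed: int = 0,
                      embedding_params: Optional[EmbeddingParams] = None,
                      svm_folds: int = 5, svm_reps: int = 5,
                      lasso_folds: int = 3,
                      boruta_max_iter: int = 100,
                      boruta_alpha: float = 0.01,
                      boruta_trees: int = 200,
                      run_lowdim: bool = True,
                      run_sparse: bool = True,
                      run_boruta: bool = True) -> Dict:
    """Run the classification arms per group and cross-group Boruta DSC.

    Every group is processed with identical seeds and settings, so results
    are invariant to group order. Returns ``{"groups": {label: SubgroupReport},
    "cross_dsc": {(label_a, label_b): dsc}}``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    reports: Dict[str, SubgroupReport] = {}
    for label, dm in groups:
        low = sparse = bor = None
        if run_lowdim:
            emb = embed_2d(dm, params=embedding_params, seed=seed)
            low = svm_cv(emb, folds=svm_folds, repetitions=svm_reps, seed=seed)
        if run_sparse:
            sparse = lasso_cv(dm, folds=lasso_folds, seed=seed)
        if run_boruta:
            bor = boruta(dm, max_iter=boruta_max_iter, alpha=boruta_alpha,
                         seed=seed, n_trees=boruta_trees)
        reports[label] = SubgroupReport(
            label=label, n_subjects=dm.n_subjects,
            lowdim=low, sparse=sparse, boruta=bor,
        )
    cross = {}
    labels = [g[0] for g in groups]
    if run_boruta:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                cross[(a, b)] = dsc(reports[a].boruta.selection_mask,
                                    reports[b].boruta.selection_mask)
    return {"groups": reports, "cross_dsc": cross}
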