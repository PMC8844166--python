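"""Voxel-wise laterality quotient (LQ) maps.

LQ = (R - L) / (R + L) per homologous voxel pair of *unstandardized*
VBM-like (non-negative) hemisphere volumes; positive values indicate
rightward asymmetry. Values are bounded in [-1, 1]; voxels with R + L = 0
are undefined (stored as NaN) and excluded from all downstream counts
rather than masquerading as perfectly symmetric zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .volume_io import BrainVolume, HemispherePair

__all__ = ["LQMap", "lq_map", "mean_lq", "threshold_lq", "lq_stack"]


@dataclass
class LQMap:
    """Per-subject or cohort-mean laterality quotient image.

    ``values`` holds NaN at undefined voxels (R+L=0 or outside the mask).
    """

    values: np.ndarray
    affine: np.ndarray
    n_subjects: int = 1
    is_mean: bool = False

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def lq_map(pair: HemispherePair, mask: Optional[BrainVolume] = None) -> LQMap:
    """Laterality quotient (R - L)/(R + L) of one hemisphere pair.

    Inputs must be non-negative (the quotient is undefined for signed
    data). Swapping the hemispheres negates every defined voxel.
    """
    L = pair.left_mirrored.values.astype(np.float64)
    R = pair.right.values.astype(np.float64)
    m = np.ones(L.shape, dtype=bool) if mask is None else mask.values.astype(bool)
    if (L[m] < 0).any() or (R[m] < 0).any():
        raise ValueError("negative VBM values: LQ undefined for signed data")
    denom = R + L
    out = np.full(L.shape, np.nan)
    ok = m & (denom > 0)
    out[ok] = (R[ok] - L[ok]) / denom[ok]
    return LQMap(out, pair.right.affine.copy(), n_subjects=1, is_mean=False)


def mean_lq(maps: Iterable[LQMap]) -> LQMap:
    """Voxel-wise mean LQ over maps, ignoring voxels undefined in a map."""
    maps = list(maps)
    if not maps:
        raise ValueError("mean_lq needs at least one map")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("LQ maps do not share a grid")
    stack = np.stack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(stack).sum(axis=0)
        mean = np.where(counts > 0, np.nansum(stack, axis=0), np.nan)
        mean = mean / np.where(counts > 0, counts, 1)
    mean[counts == 0] = np.nan
    return LQMap(mean, maps[0].affine.copy(),
                 n_subjects=sum(m.n_subjects for m in maps), is_mean=True)


def lq_stack(pairs, mask: Optional[BrainVolume] = None) -> np.ndarray:
    """Subjects x V matrix of LQ values sampled at in-mask voxels.

    Column order is the C-order mask scan (same convention as
    :func:`hemiclass.prep.build_data_matrix`).
    """
    pairs = sorted(pairs, key=lambda p: p.subject_id)
    maps = [lq_map(p, mask) for p in pairs]
    if mask is None:
        coords = np.argwhere(np.ones(maps[0].values.shape, dtype=bool))
    else:
        coords = np.argwhere(mask.values.astype(bool))
    i, j, k = coords.T
    return np.stack([m.values[i, j, k] for m in maps])


def threshold_lq(lq: LQMap, t: float, direction: str) -> BrainVolume:
    """Binary directional asymmetry map at threshold ``t > 0``.

    ``rightward`` marks voxels with LQ >= t, ``leftward`` those with
    LQ <= -t; undefined voxels are never marked.
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    if direction not in ("rightward", "leftward"):
        raise ValueError("direction must be 'rightward' or 'leftward'")
    vals = lq.values
    with np.errstate(invalid="ignore"):
        if direction == "rightward":
            binary = vals >= t
        else:
            binary = vals <= -t
    binary &= np.isfinite(vals)
    return BrainVolume(binary.astype(np.uint8), lq.affine.copy(), side="none")
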