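"""Spatial agreement between binary asymmetry maps.

Dice similarity coefficient DSC = 2|A n B| / (|A| + |B|), threshold sweeps
of a mean-LQ map against a candidate map, and a generic connected-component
summary against an optional integer label volume (in place of any specific
atlas lookup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .laterality import LQMap, threshold_lq
from .volume_io import BrainVolume

__all__ = ["DSCCurve", "dsc", "dsc_curve", "default_threshold_grid",
           "cluster_label_summary"]


#: LQ threshold sweep grid: 0.02 to 0.60 in steps of 0.02. A coarser decade
#: (0.2..6) would leave the bounded quotient |LQ| <= 1 with at most three
#: usable thresholds; the fine grid resolves peaks in the few-percent range.
def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(1, 31) * 0.02, 10)


@dataclass
class DSCCurve:
    thresholds: np.ndarray
    dsc_values: np.ndarray
    direction: str
    reference_name: str = "mean_lq"
    comparison_name: str = "candidate"

    def peak(self):
        """(threshold, dsc) at the curve maximum (first on ties)."""
        i = int(np.argmax(self.dsc_values))
        return float(self.thresholds[i]), float(self.dsc_values[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "dsc": self.dsc_values,
                             "direction": self.direction})


def _as_binary(v: Union[BrainVolume, np.ndarray]) -> np.ndarray:
    arr = v.values if isinstance(v, BrainVolume) else np.asarray(v)
    return arr.astype(bool)


def dsc(a: Union[BrainVolume, np.ndarray], b: Union[BrainVolume, np.ndarray]) -> float:
    """Dice similarity coefficient of two binary maps on a shared grid.

    Two empty maps give 0 with a warning (keeps sweep curves plottable).
    """
    A, B = _as_binary(a), _as_binary(b)
    if A.shape != B.shape:
        raise ValueError(f"grid mismatch: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        warnings.warn("DSC of two empty maps defined as 0", RuntimeWarning)
        return 0.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def dsc_curve(lq_mean: LQMap, candidate: Union[BrainVolume, np.ndarray],
              grid: Optional[np.ndarray] = None,
              direction: str = "rightward",
              comparison_name: str = "candidate") -> DSCCurve:
    """DSC between directional LQ-threshold maps and a candidate map, over a
    strictly increasing grid of positive thresholds."""
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.array([dsc(threshold_lq(lq_mean, t, direction), candidate)
                         for t in grid])
    return DSCCurve(thresholds=grid, dsc_values=vals, direction=direction,
                    comparison_name=comparison_name)


def cluster_label_summary(binary: Union[BrainVolume, np.ndarray],
                          labels: Optional[Union[BrainVolume, np.ndarray]] = None
                          ) -> pd.DataFrame:
    """Connected components (26-connectivity) of a binary map.

    Returns one row per component (columns: component, size, centroid_x/y/z)
    or, when an integer label volume is supplied, one row per
    component-label pair with the overlap fraction of the component inside
    that label value.
    """
    B = _as_binary(binary)
    struct = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(B, structure=struct)
    rows = []
    lab_arr = None
    if labels is not None:
        lab_arr = (labels.values if isinstance(labels, BrainVolume)
                   else np.asarray(labels)).astype(int)
        if lab_arr.shape != B.shape:
            raise ValueError("label volume grid mismatch")
    for c in range(1, n + 1):
        comp = lab == c
        size = int(comp.sum())
        cx, cy, cz = ndimage.center_of_mass(comp)
        base = {"component": c, "size": size,
                "centroid_x": cx, "centroid_y": cy, "centroid_z": cz}
        if lab_arr is None:
            rows.append(base)
        else:
            vals, counts = np.unique(lab_arr[comp], return_counts=True)
            for v, cnt in zip(vals, counts):
                rows.append({**base, "label": int(v),
                             "overlap": cnt / size})
    cols = ["component", "size", "centroid_x", "centroid_y", "centroid_z"]
    if lab_arr is not None:
        cols += ["label", "overlap"]
    return pd.DataFrame(rows, columns=cols)
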