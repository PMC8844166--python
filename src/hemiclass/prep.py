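"""Hemisphere standardization and assembly of the N x V data matrix.

Each hemisphere is z-scored *within itself* across mask voxels (population
denominator). This removes the global left/right difference in mean
volumetry so classifiers cannot succeed on the mean offset alone; whatever
classifiability remains must come from the spatial pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .volume_io import BrainVolume, HemispherePair

__all__ = [
    "DataMatrix",
    "zscore_hemisphere",
    "build_data_matrix",
    "vectorize",
    "devectorize",
    "read_participants",
    "save_matrix",
    "load_matrix",
]


@dataclass
class DataMatrix:
    """Hemisphere-by-voxel matrix with row/column provenance.

    Rows are ordered by subject_id (sorted), left before right, so
    N = 2 x number of subjects. Every row is z-scored (mean 0, population
    sd 1 over the mask). ``voxel_index`` maps column j to its 3-D grid
    coordinate (C-order scan of the mask).
    """

    X: np.ndarray                      # (N, V) float64, z-units
    side_labels: np.ndarray            # (N,) of {"left", "right"}
    subject_ids: np.ndarray            # (N,) strings, each id twice
    voxel_index: np.ndarray            # (V, 3) int
    grid_shape: tuple
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    groups: Optional[pd.DataFrame] = None   # indexed by participant_id

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0] // 2

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def side_targets(self) -> np.ndarray:
        """Side labels encoded -1 (left) / +1 (right)."""
        return np.where(self.side_labels == "right", 1, -1)

    def rows_for(self, subject_ids: Sequence[str]) -> "DataMatrix":
        """Sub-matrix keeping both hemispheres of the given subjects."""
        keep = np.isin(self.subject_ids, list(subject_ids))
        groups = None
        if self.groups is not None:
            groups = self.groups.loc[self.groups.index.isin(subject_ids)]
        return DataMatrix(self.X[keep], self.side_labels[keep],
                          self.subject_ids[keep], self.voxel_index,
                          self.grid_shape, self.affine, groups)


def zscore_hemisphere(hemi: BrainVolume, mask: BrainVolume) -> BrainVolume:
    """Standardize a hemisphere to mean 0, sd 1 within the mask.

    Population (n) denominator; out-of-mask voxels are set to 0. Adding a
    constant to all in-mask values leaves the output unchanged.
    """
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    vals = hemi.values[m].astype(float)
    sd = vals.std()  # population denominator
    if sd == 0:
        raise ValueError("zero variance within mask: degenerate hemisphere")
    out = np.zeros_like(hemi.values, dtype=np.float64)
    out[m] = (vals - vals.mean()) / sd
    return BrainVolume(out, hemi.affine.copy(), side=hemi.side,
                       subject_id=hemi.subject_id)


def mask_coordinates(mask: BrainVolume) -> np.ndarray:
    """C-order (x, y, z) coordinates of in-mask voxels, shape (V, 3)."""
    return np.argwhere(mask.values.astype(bool))


def vectorize(vol: BrainVolume, voxel_index: np.ndarray) -> np.ndarray:
    """Sample a volume at the given coordinates into a length-V vector."""
    i, j, k = voxel_index.T
    return vol.values[i, j, k].astype(np.float64)


def devectorize(row: np.ndarray, voxel_index: np.ndarray, grid_shape,
                affine: Optional[np.ndarray] = None) -> BrainVolume:
    """Place a length-V vector back on the 3-D grid (zeros elsewhere)."""
    row = np.asarray(row)
    if row.shape[0] != voxel_index.shape[0]:
        raise ValueError(
            f"row length {row.shape[0]} does not match V={voxel_index.shape[0]}"
        )
    out = np.zeros(tuple(grid_shape), dtype=np.float64)
    i, j, k = voxel_index.T
    out[i, j, k] = row
    return BrainVolume(out, np.eye(4) if affine is None else affine,
                       side="none")


def build_data_matrix(pairs: Iterable[HemispherePair], mask: BrainVolume,
                      participants: Optional[pd.DataFrame] = None) -> DataMatrix:
    """Z-score every hemisphere and stack them into an N x V matrix.

    Rows are sorted by subject_id with the left hemisphere before the right;
    flattening order is the C-order scan of the mask, recorded in
    ``voxel_index``. Deterministic: identical inputs give bit-identical
    matrices.
    """
    pairs = sorted(pairs, key=lambda p: p.subject_id)
    ids = [p.subject_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in hemisphere pairs")
    voxel_index = mask_coordinates(mask)
    rows, sides, row_ids = [], [], []
    for p in pairs:
        if p.grid_shape != mask.grid_shape:
            raise ValueError(f"grid mismatch for subject {p.subject_id}")
        for side, vol in (("left", p.left_mirrored), ("right", p.right)):
            z = zscore_hemisphere(vol, mask)
            rows.append(vectorize(z, voxel_index))
            sides.append(side)
            row_ids.append(p.subject_id)
    groups = None
    if participants is not None:
        groups = participants.set_index("participant_id") \
            if "participant_id" in participants.columns else participants
    return DataMatrix(np.vstack(rows), np.array(sides), np.array(row_ids),
                      voxel_index, mask.grid_shape,
                      mask.affine.copy(), groups)


def read_participants(path) -> pd.DataFrame:
    """Read a BIDS-style participants TSV (participant_id, sex, handedness)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "participant_id" not in df.columns:
        raise ValueError(f"participants table {path} lacks participant_id")
    return df


def save_matrix(data: DataMatrix, path) -> Path:
    """Cache a DataMatrix to .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path, X=data.X, side_labels=data.side_labels,
        subject_ids=data.subject_ids, voxel_index=data.voxel_index,
        grid_shape=np.asarray(data.grid_shape), affine=data.affine,
    )
    meta = {"n_rows": int(data.X.shape[0]), "n_voxels": int(data.X.shape[1])}
    if data.groups is not None:
        meta["groups"] = data.groups.reset_index().to_dict(orient="list")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def load_matrix(path) -> DataMatrix:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        groups = None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "groups" in meta:
                groups = pd.DataFrame(meta["groups"]).set_index("participant_id")
        return DataMatrix(
            X=z["X"], side_labels=z["side_labels"].astype(str),
            subject_ids=z["subject_ids"].astype(str),
            voxel_index=z["voxel_index"],
            grid_shape=tuple(int(s) for s in z["grid_shape"]),
            affine=z["affine"], groups=groups,
        )
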