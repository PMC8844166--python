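"""Volumetric image handling: reading, midline splitting, and left-right mirroring.

Volumes are assumed to live on a left-right symmetric template grid so that,
after splitting at the midsagittal boundary and flipping the left hemisphere
across the X-axis, voxel ``(i, j, k)`` of the mirrored left hemisphere is the
anatomical homologue of voxel ``(i, j, k)`` of the right hemisphere.

Left and right are identified from the affine's world axes (positive world-x
is the subject's right), never from array storage order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import nibabel as nib
import numpy as np

__all__ = [
    "BrainVolume",
    "HemispherePair",
    "read_volume",
    "write_volume",
    "split_hemispheres",
    "flip_lr",
    "make_common_mask",
]


@dataclass
class BrainVolume:
    """A 3-D scalar grid with its voxel-to-world affine.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z)
        Scalar image data (arbitrary intensity units; VBM gray-matter volume
        in the intended application).
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm transform (NIfTI convention, RAS+ world).
    side : {"left", "right", "whole", "none"}
        Hemisphere tag; ``whole`` before splitting, ``left``/``right`` after.
    subject_id : str, optional
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    side: str = "whole"
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.values.ndim}-D data"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.side not in ("left", "right", "whole", "none"):
            raise ValueError(f"invalid side tag {self.side!r}")

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape

    def lr_axis(self) -> int:
        """Array axis most aligned with the world left-right (x) axis."""
        return int(np.argmax(np.abs(self.affine[0, :3])))

    def copy(self) -> "BrainVolume":
        return replace(self, values=self.values.copy(), affine=self.affine.copy())


@dataclass
class HemispherePair:
    """One subject's two hemispheres in voxel-wise correspondence.

    ``left_mirrored`` has already been flipped across the X-axis so that
    voxel (i, j, k) in it is the mirror-homologue of (i, j, k) in ``right``.
    """

    left_mirrored: BrainVolume
    right: BrainVolume
    subject_id: str

    def __post_init__(self) -> None:
        if self.left_mirrored.side != "left":
            raise ValueError("left_mirrored must carry side='left'")
        if self.right.side != "right":
            raise ValueError("right must carry side='right'")
        if self.left_mirrored.grid_shape != self.right.grid_shape:
            raise ValueError("hemisphere grids differ within a pair")

    @property
    def grid_shape(self) -> tuple:
        return self.right.grid_shape


def read_volume(path) -> BrainVolume:
    """Read a 3-D NIfTI-1 image (plain or gzipped).

    Raises a format error naming the offending dimensionality for non-3-D
    images (e.g. 4-D series).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - message passthrough
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"expected 3-D volume, got {data.ndim}-D image in {path}"
        )
    return BrainVolume(values=np.asarray(data, dtype=np.float64),
                       affine=np.asarray(img.affine, dtype=float))


def write_volume(vol: BrainVolume, path, dtype=None) -> Path:
    """Write a BrainVolume as NIfTI-1; masks should pass ``dtype=np.uint8``."""
    path = Path(path)
    data = vol.values
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    return path


def _x_direction(vol: BrainVolume) -> int:
    """+1 if increasing index along the LR axis moves toward world +x (right)."""
    ax = vol.lr_axis()
    return 1 if vol.affine[0, ax] > 0 else -1


def split_hemispheres(vol: BrainVolume, midline_index: int):
    """Split a whole-brain volume into (left, right) at the midsagittal boundary.

    The split is half-open at the boundary *before* voxel column
    ``midline_index`` along the left-right axis: indices ``[0, m)`` fall on
    one side and ``[m, X)`` on the other. The two halves must have equal
    x-extent, which requires an even x-extent and ``m = X/2``; grids that
    cannot be split evenly are rejected (pad to a symmetric template grid
    instead of silently trimming).
    """
    if vol.side != "whole":
        raise ValueError("split_hemispheres requires a whole-brain volume")
    ax = vol.lr_axis()
    extent = vol.values.shape[ax]
    if not (0 < midline_index < extent):
        raise ValueError(
            f"midline_index must lie strictly inside (0, {extent}); got {midline_index}"
        )
    lo, hi = midline_index, extent - midline_index
    if lo != hi:
        raise ValueError(
            f"unequal hemisphere extents {lo} and {hi}: pad the image or use a "
            "left-right symmetric template grid with an even x-extent"
        )

    def _take(start, stop):
        sl = [slice(None)] * 3
        sl[ax] = slice(start, stop)
        sub = vol.values[tuple(sl)].copy()
        aff = vol.affine.copy()
        # shift the origin so voxel 0 of the sub-volume maps correctly
        aff[:3, 3] = aff[:3, 3] + aff[:3, ax] * start
        return sub, aff

    first, first_aff = _take(0, midline_index)
    second, second_aff = _take(midline_index, extent)
    if _x_direction(vol) > 0:
        left = BrainVolume(first, first_aff, side="left", subject_id=vol.subject_id)
        right = BrainVolume(second, second_aff, side="right", subject_id=vol.subject_id)
    else:
        right = BrainVolume(first, first_aff, side="right", subject_id=vol.subject_id)
        left = BrainVolume(second, second_aff, side="left", subject_id=vol.subject_id)
    return left, right


def flip_lr(hemi: BrainVolume) -> BrainVolume:
    """Mirror a left hemisphere across the midsagittal plane (world x=0).

    The array is reversed along the left-right axis and the affine updated so
    world coordinates map ``x -> -x``; on a symmetric template centred at
    x=0 this lands each left-hemisphere voxel on its right homologue.
    The side tag remains ``left``. The transform is an involution.
    """
    if hemi.side != "left":
        raise ValueError("flip_lr applies to side='left' volumes only")
    ax = hemi.lr_axis()
    n = hemi.values.shape[ax]
    values = np.flip(hemi.values, axis=ax).copy()
    # re-index: new voxel i held old voxel n-1-i
    aff = hemi.affine.copy()
    aff[:3, 3] = aff[:3, 3] + aff[:3, ax] * (n - 1)
    aff[:3, ax] = -aff[:3, ax]
    # mirror the world about the midsagittal plane x=0
    mirror = np.diag([-1.0, 1.0, 1.0, 1.0])
    aff = mirror @ aff
    return BrainVolume(values, aff, side="left", subject_id=hemi.subject_id)


def make_common_mask(pairs: Iterable[HemispherePair], min_value: float = 0.0) -> BrainVolume:
    """Cohort-intersection mask: 1 where the value exceeds ``min_value`` in
    every hemisphere of every pair.

    The surviving voxel count V is ``int(mask.values.sum())``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no hemisphere pairs given")
    shape = pairs[0].grid_shape
    mask = np.ones(shape, dtype=bool)
    for p in pairs:
        if p.grid_shape != shape:
            raise ValueError("hemisphere pairs do not share a grid")
        mask &= p.left_mirrored.values > min_value
        mask &= p.right.values > min_value
    if not mask.any():
        raise ValueError("no voxels survive masking")
    return BrainVolume(mask.astype(np.uint8), pairs[0].right.affine.copy(),
                       side="none")
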