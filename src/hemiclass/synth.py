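"""Seeded synthetic cohorts of hemisphere pairs with known asymmetry.

The generator emulates gray-matter volume maps on a symmetric template:
a shared smooth bilateral template, a smooth subject-level random field
common to both sides, side-specific effects planted in configurable
regions, optional global side offset, optional extra right-hemisphere
spread, sex/handedness modulation of the planted effects, and independent
voxel noise. Planted rightward effects scale the left hemisphere by
(1 - delta) / (1 + delta), which makes the noise-free voxel-wise laterality
quotient exactly delta in the region — the ground truth is closed-form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BrainVolume, HemispherePair, write_volume, read_volume

__all__ = ["PlantedRegion", "SynthConfig", "generate_cohort", "write_cohort",
           "read_cohort"]


@dataclass
class PlantedRegion:
    """An axis-aligned block with a side-specific relative effect.

    ``block`` is ((x0, x1), (y0, y1), (z0, z1)) in hemisphere voxel indices
    (half-open); ``side`` is the direction of the larger volume
    ("rightward" or "leftward"); ``delta`` is the expected laterality
    quotient magnitude in the region, in (-1, 1) exclusive.
    """

    block: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]
    side: str = "rightward"
    delta: float = 0.2

    def slices(self):
        return tuple(slice(lo, hi) for lo, hi in self.block)

    def voxels(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.slices()] = True
        return np.argwhere(m)


@dataclass
class SynthConfig:
    """Study conditions of a synthetic cohort.

    grid_shape is the per-hemisphere grid. Units follow VBM gray-matter
    volume maps: template values sit in roughly [0.3, 0.8] (dimensionless
    tissue-volume fraction), subject_sd and noise_sd are on the same scale.
    side_spread_ratio >= 1 multiplies the right hemisphere's subject-level
    deviation from the template, giving right hemispheres the larger
    between-subject spread. group_effects maps a participants column to
    per-value multipliers of every planted delta, e.g.
    ``{"column": "handedness", "modifiers": {"right": 1.0, "left": 0.5}}``.
    """

    n_subjects: int = 100
    grid_shape: Tuple[int, int, int] = (12, 12, 12)
    planted_regions: Sequence[PlantedRegion] = ()
    subject_sd: float = 0.05
    noise_sd: float = 0.05
    global_side_offset: float = 0.0
    side_spread_ratio: float = 1.0
    group_effects: Optional[dict] = None
    smooth_sigma: float = 1.5
    template_range: Tuple[float, float] = (0.3, 0.8)
    sex_probs: Tuple[float, float] = (0.55, 0.45)        # F, M
    hand_probs: Tuple[float, float, float] = (0.80, 0.17, 0.03)  # R, L, ambi
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.subject_sd < 0 or self.noise_sd < 0:
            problems.append("standard deviations must be non-negative")
        if self.side_spread_ratio < 1:
            problems.append("side_spread_ratio must be >= 1")
        for r in self.planted_regions:
            if not (-1 < r.delta < 1):
                problems.append(f"delta {r.delta} outside (-1, 1)")
            if r.side not in ("rightward", "leftward"):
                problems.append(f"invalid region side {r.side!r}")
            for (lo, hi), extent in zip(r.block, self.grid_shape):
                if not (0 <= lo < hi <= extent):
                    problems.append(f"planted block {r.block} outside grid")
        if problems:
            raise ValueError("invalid SynthConfig: " + "; ".join(problems))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-sd smooth random field (Gaussian-blurred white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _participants(rng: np.random.Generator, cfg: SynthConfig) -> pd.DataFrame:
    n = cfg.n_subjects
    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    sex = rng.choice(["F", "M"], size=n, p=cfg.sex_probs)
    hand = rng.choice(["right", "left", "ambidextrous"], size=n,
                      p=cfg.hand_probs)
    return pd.DataFrame({"participant_id": ids, "sex": sex,
                         "handedness": hand})


def _delta_multiplier(cfg: SynthConfig, row: pd.Series) -> float:
    ge = cfg.group_effects
    if not ge:
        return 1.0
    val = row[ge["column"]]
    return float(ge["modifiers"].get(val, 1.0))


def generate_cohort(cfg: SynthConfig):
    """Generate (pairs, participants, truth) for a synthetic cohort.

    Per subject: template + smooth subject field shared by both sides; the
    hemisphere opposite each planted region is scaled by
    (1 - d)/(1 + d) with d = delta x group multiplier, making the expected
    LQ in the region exactly d; independent voxel noise per side; the
    global offset added to the right side; the right side's subject field
    scaled by side_spread_ratio. All values are clipped non-negative.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.grid_shape)
    lo, hi = cfg.template_range
    template = lo + (hi - lo) * (
        _smooth_field(rng, shape, cfg.smooth_sigma) * 0.15 + 0.5
    ).clip(0.05, 0.95)
    participants = _participants(rng, cfg)
    affine = np.eye(4)
    affine[0, 3] = 0.5  # hemisphere grid sits right of the midplane x=0

    pairs = []
    for _, row in participants.iterrows():
        sid = row["participant_id"]
        subj_field = cfg.subject_sd * _smooth_field(rng, shape, cfg.smooth_sigma)
        left = template + subj_field
        right = template + cfg.side_spread_ratio * subj_field
        mult = _delta_multiplier(cfg, row)
        for reg in cfg.planted_regions:
            d = reg.delta * mult
            factor = (1 - d) / (1 + d)
            sl = reg.slices()
            if reg.side == "rightward":
                left[sl] = left[sl] * factor
            else:
                right[sl] = right[sl] * factor
        if cfg.noise_sd > 0:
            left = left + cfg.noise_sd * rng.standard_normal(shape)
            right = right + cfg.noise_sd * rng.standard_normal(shape)
        right = right + cfg.global_side_offset
        left = np.clip(left, 0, None)
        right = np.clip(right, 0, None)
        pairs.append(HemispherePair(
            left_mirrored=BrainVolume(left, affine.copy(), side="left",
                                      subject_id=sid),
            right=BrainVolume(right, affine.copy(), side="right",
                              subject_id=sid),
            subject_id=sid,
        ))

    truth = {
        "seed": int(cfg.seed),
        "grid_shape": list(shape),
        "planted_regions": [
            {
                "block": [list(b) for b in reg.block],
                "side": reg.side,
                "expected_lq": reg.delta if reg.side == "rightward"
                else -reg.delta,
                "voxels": reg.voxels(shape).tolist(),
            }
            for reg in cfg.planted_regions
        ],
        "global_side_offset": cfg.global_side_offset,
        "side_spread_ratio": cfg.side_spread_ratio,
    }
    return pairs, participants, truth


def planted_voxel_mask(truth: dict) -> np.ndarray:
    """Boolean hemisphere-grid mask of all planted voxels in a truth record."""
    m = np.zeros(tuple(truth["grid_shape"]), dtype=bool)
    for reg in truth["planted_regions"]:
        sl = tuple(slice(lo, hi) for lo, hi in reg["block"])
        m[sl] = True
    return m


def write_cohort(pairs, participants: pd.DataFrame, truth: dict, out_dir):
    """Write one NIfTI per hemisphere (sub-XXX_hemi-{L,R}.nii.gz; the L file
    already mirrored onto the right grid), participants.tsv and truth.json;
    returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in pairs:
        for tag, vol in (("L", p.left_mirrored), ("R", p.right)):
            path = out / f"{p.subject_id}_hemi-{tag}.nii.gz"
            write_volume(vol, path, dtype=np.float32)
            manifest.append(path)
    ppath = out / "participants.tsv"
    participants.to_csv(ppath, sep="\t", index=False)
    manifest.append(ppath)
    tpath = out / "truth.json"
    tpath.write_text(json.dumps(truth, sort_keys=True))
    manifest.append(tpath)
    return manifest


def read_cohort(in_dir):
    """Re-read a written cohort into (pairs, participants, truth)."""
    in_dir = Path(in_dir)
    participants = pd.read_csv(in_dir / "participants.tsv", sep="\t")
    truth = json.loads((in_dir / "truth.json").read_text())
    pairs = []
    for sid in participants["participant_id"]:
        left = read_volume(in_dir / f"{sid}_hemi-L.nii.gz")
        right = read_volume(in_dir / f"{sid}_hemi-R.nii.gz")
        left.side, right.side = "left", "right"
        left.subject_id = right.subject_id = sid
        pairs.append(HemispherePair(left_mirrored=left, right=right,
                                    subject_id=sid))
    return pairs, participants, truth
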