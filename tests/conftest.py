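import warnings

import numpy as np
import pytest

from hemiclass import (BrainVolume, DataMatrix, HemispherePair, PlantedRegion,
                       SynthConfig, build_data_matrix, generate_cohort,
                       make_common_mask)

from sklearn.exceptions import ConvergenceWarning

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=ConvergenceWarning)


def make_pair(left_vals, right_vals, subject_id="sub-001", affine=None):
    aff = np.eye(4) if affine is None else affine
    return HemispherePair(
        left_mirrored=BrainVolume(np.asarray(left_vals, float), aff.copy(),
                                  side="left", subject_id=subject_id),
        right=BrainVolume(np.asarray(right_vals, float), aff.copy(),
                          side="right", subject_id=subject_id),
        subject_id=subject_id,
    )


def random_matrix(rng, n_subjects=20, V=50) -> DataMatrix:
    """A synthetic DataMatrix with z-scored random rows (no side signal)."""
    X = rng.standard_normal((2 * n_subjects, V))
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    sides = np.array(["left", "right"] * n_subjects)
    ids = np.array([f"sub-{i // 2:03d}" for i in range(2 * n_subjects)])
    coords = np.argwhere(np.ones((V, 1, 1), dtype=bool))
    return DataMatrix(X, sides, ids, coords, (V, 1, 1))


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort shared by several tests: one rightward block."""
    cfg = SynthConfig(
        n_subjects=30, grid_shape=(8, 8, 4),
        planted_regions=[PlantedRegion(((2, 4), (2, 6), (1, 3)),
                                       "rightward", 0.15)],
        subject_sd=0.05, noise_sd=0.03, seed=7,
    )
    pairs, participants, truth = generate_cohort(cfg)
    mask = make_common_mask(pairs, 0.0)
    dm = build_data_matrix(pairs, mask, participants)
    return {"cfg": cfg, "pairs": pairs, "participants": participants,
            "truth": truth, "mask": mask, "dm": dm}
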