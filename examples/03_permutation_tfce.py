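"""One-sample sign-flip permutation test with TFCE on laterality maps.

Tests, voxel by voxel, whether the laterality quotient differs from zero
across subjects, enhancing spatially contiguous effects with TFCE and
controlling the family-wise error rate with the permutation distribution of
the image-wide maximum.
"""

import numpy as np

from hemiclass import (PlantedRegion, SynthConfig, generate_cohort, lq_stack,
                       make_common_mask, sign_flip_test)
from hemiclass.synth import planted_voxel_mask

cfg = SynthConfig(
    n_subjects=30, grid_shape=(10, 10, 6),
    planted_regions=[PlantedRegion(((2, 5), (2, 6), (1, 4)),
                                   "rightward", 0.10)],
    subject_sd=0.05, noise_sd=0.03, seed=7,
)
pairs, _, truth = generate_cohort(cfg)
mask = make_common_mask(pairs, 0.0)

rows = np.nan_to_num(lq_stack(pairs, mask))      # subjects x voxels
result = sign_flip_test(rows, mask.values.astype(bool),
                        n_perm=1000, seed=1)

sig = result.significant(0.05)
planted = planted_voxel_mask(truth)
print(f"{int(sig.sum())} voxels significant at p_fwe < 0.05 "
      f"({int(planted.sum())} voxels planted)")
print(f"sensitivity inside planted block: {sig[planted].mean():.2f}")
print(f"false positives elsewhere       : {int(sig[~planted].sum())}")
print(f"max |t| = {np.nanmax(np.abs(result.t_map)):.2f}, "
      f"null maxima 95th pct = {np.quantile(result.null_maxima[:, 0], .95):.2f}")
# The planted block should light up almost completely while the rest of the
# mask stays clean — the hallmark of FWE-controlled inference.
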