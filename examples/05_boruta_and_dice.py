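"""All-relevant voxel selection and Dice comparison against laterality maps.

Runs Boruta (shadow-feature random-forest selection) next to the TFCE
t-test on a cohort mixing weak and strong asymmetries, then sweeps Dice
similarity between each result map and thresholded mean-LQ maps. The
t-test map agrees best with low thresholds (it flags any reliable
asymmetry); the Boruta map agrees best with higher ones (it keeps only
strongly discriminative voxels).
"""

import numpy as np

from hemiclass import (PlantedRegion, SynthConfig, boruta, build_data_matrix,
                       dsc, dsc_curve, generate_cohort, lq_map, lq_stack,
                       make_common_mask, mean_lq, sign_flip_test)

regions = [PlantedRegion(((0, 2), (0, 4), (0, 2)), "rightward", 0.04),
           PlantedRegion(((7, 10), (6, 9), (3, 5)), "leftward", 0.05),
           PlantedRegion(((2, 4), (5, 8), (1, 3)), "rightward", 0.20),
           PlantedRegion(((6, 9), (0, 3), (0, 2)), "leftward", 0.18)]
cfg = SynthConfig(n_subjects=40, grid_shape=(10, 10, 5),
                  planted_regions=regions, subject_sd=0.05, noise_sd=0.03,
                  seed=3)
pairs, participants, _ = generate_cohort(cfg)
mask = make_common_mask(pairs, 0.0)
dm = build_data_matrix(pairs, mask, participants)

rows = np.nan_to_num(lq_stack(pairs, mask))
tfce_res = sign_flip_test(rows, mask.values.astype(bool), n_perm=500, seed=1)
sig_right = tfce_res.significant() & (np.nan_to_num(tfce_res.t_map) > 0)

selection = boruta(dm, max_iter=30, seed=1)
print(f"t-test: {int(tfce_res.significant().sum())} significant voxels; "
      f"Boruta: {selection.counts()}")
print(f"DSC(t-test map, Boruta map) = "
      f"{dsc(tfce_res.significant(), selection.selection_mask.values > 0):.3f}")

mean_map = mean_lq([lq_map(p, mask) for p in pairs])
curve_t = dsc_curve(mean_map, sig_right, direction="rightward")
curve_b = dsc_curve(mean_map, selection.selection_mask.values > 0,
                    direction="rightward")
tt, td = curve_t.peak()
bt, bd = curve_b.peak()
print(f"t-test curve peaks at LQ threshold {tt:.2f} (DSC {td:.2f})")
print(f"Boruta curve peaks at LQ threshold {bt:.2f} (DSC {bd:.2f})")
# The Boruta peak sits at a strictly higher threshold: the two methods are
# complementary views of the asymmetry landscape.
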