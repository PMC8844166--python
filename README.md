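# hemiclass

**Hemisphere classifiability of volumetric brain maps.**

Most asymmetry studies ask *where* the left and right hemispheres differ.
`hemiclass` asks a complementary question: *how accurately can a
hemisphere be identified as left or right*, and which voxels drive that
classifiability? Given gray-matter volume maps (or any scalar volumetric
measure) co-registered to a left–right symmetric template, the package

- splits each brain at the midsagittal boundary and mirrors the left
  hemisphere onto the right so voxel indices correspond across sides;
- builds voxel-wise **laterality quotient** maps,
  `LQ = (R − L)/(R + L) ∈ [−1, 1]` (positive = rightward asymmetry), and
  tests them against zero with a **one-sample sign-flip permutation test
  with threshold-free cluster enhancement (TFCE)** and family-wise error
  control — implemented in-package, seeded and reproducible;
- z-scores each hemisphere, stacks them into an N×V matrix
  (N = 2 × subjects) and classifies side two ways: a **low-dimensional
  arm** (joint UMAP embedding to 2-D + linear SVM under repeated
  stratified CV) and a **high-dimensional arm** (L1-sparse linear
  classification per voxel);
- localizes classifier-relevant voxels with **Boruta** all-relevant
  selection (shadow features + random forest + binomial decisions);
- compares the resulting binary maps (TFCE-significant, Boruta-selected,
  thresholded LQ) with **Dice similarity coefficients** across a sweep of
  laterality thresholds, and reruns both arms within **subgroups** (sex,
  handedness) with cross-group map overlap.

A first-class synthetic-cohort generator plants asymmetries with
closed-form ground truth (`LQ` exactly δ in a planted region), so every
stage is testable end-to-end without downloading any data.

Intended users: neuroimaging researchers studying structural asymmetry
who already have template-space volumes (e.g. VBM output) and want a
reproducible, dependency-light classifiability analysis.

## Worked example

```python
import numpy as np
from hemiclass import (PlantedRegion, SynthConfig, generate_cohort,
                       make_common_mask, build_data_matrix, embed_2d,
                       svm_cv, lasso_cv, variance_ftest)

regions = [PlantedRegion(((0, 4), (0, 5), (0, 3)), "rightward", 0.15),
           PlantedRegion(((5, 10), (5, 10), (2, 5)), "leftward", 0.12),
           PlantedRegion(((6, 10), (0, 4), (0, 2)), "rightward", 0.10)]
cfg = SynthConfig(n_subjects=60, grid_shape=(10, 10, 5),
                  planted_regions=regions, side_spread_ratio=2.0,
                  subject_sd=0.05, noise_sd=0.03, seed=0)
pairs, participants, _ = generate_cohort(cfg)
mask = make_common_mask(pairs, 0.0)
dm = build_data_matrix(pairs, mask, participants)

emb = embed_2d(dm, seed=0)
report = svm_cv(emb, folds=5, repetitions=5, seed=0)
F, p = variance_ftest(emb, 1)
sparse = lasso_cv(dm, folds=3, seed=0)
print(report.mean_accuracy, F, sparse.report.mean_accuracy)
```

Running this (it is `examples/04_classify_hemispheres.py`) prints:

```
data matrix: 120 hemispheres x 496 voxels
low-dim  CV accuracy 0.802 (range 0.625-0.917)
precision left 0.780, right 0.848
embedding spread right/left: F = 3.38 (p = 6.01e-06)
high-dim CV accuracy 0.992, 25 voxels with nonzero weight
```

Reading the numbers: the 2-D embedding keeps enough of the planted
left/right pattern to classify sides at 0.80 accuracy; the right
hemispheres spread more than the left (variance ratio F = 3.4, mirrored in
the higher right-class precision); and the voxel-wise sparse classifier is
near ceiling, as expected when each voxel is its own feature. The
`examples/` directory holds one short script per capability (splitting and
mirroring, LQ maps, permutation TFCE, classification, Boruta + Dice
sweeps, subgroups); each prints what it computes and what the numbers
mean.

## Command line

A thin CLI wraps the same library functions:

```bash
hemiclass synth --n-subjects 20 --seed 1 --out-dir cohort/
hemiclass prep  --in-dir cohort/ --out matrix.npz
hemiclass tfce  --lq4d lq_stack4d.nii.gz --mask mask.nii.gz --n-perm 5000 --seed 1
hemiclass classify-low  --matrix matrix.npz --out low.json
hemiclass classify-high --matrix matrix.npz --out-prefix lasso_
hemiclass boruta --matrix matrix.npz --out boruta_mask.nii.gz
hemiclass all --config config.yaml --out-dir run/ --seed 1
```

`hemiclass all` runs the whole pipeline from one YAML config and writes a
run log with every default it used.

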