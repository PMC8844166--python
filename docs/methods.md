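# Methods

`hemiclass` asks a classification question about brain asymmetry: given
gray-matter volume maps registered to a left–right symmetric template, how
accurately can each hemisphere be identified as left or right, and which
voxels carry that information? The package implements the full chain —
hemisphere splitting and mirroring, per-hemisphere standardization,
voxel-wise laterality quotients, a permutation TFCE test, a 2-D manifold
classification arm, a voxel-wise sparse classification arm, all-relevant
feature selection, and Dice-based map comparison — together with a
synthetic-cohort generator that makes every stage testable with closed-form
ground truth.

## Hemisphere geometry

Volumes are assumed co-registered to a symmetric template whose midsagittal
plane is world x = 0. Left/right is read from the affine (positive world-x
is the subject's right), never from array storage order. The split is a
half-open boundary split `[0, m) / [m, X)` along the left–right axis with
`m = X/2`; odd x-extents are rejected rather than silently trimmed, because
asymmetric trimming corrupts voxel homology — pad to a symmetric grid
instead. Mirroring reverses the array along the left–right axis and
composes the affine with a reflection about x = 0, so the mirrored left
hemisphere's voxel (i, j, k) shares world coordinates with right voxel
(i, j, k). The double flip is an exact involution.

The analysis mask is the cohort intersection: voxels whose value exceeds a
floor (default 0) in every hemisphere of every subject, which guarantees
that every matrix column is observed in all rows.

## Standardization and the data matrix

Each hemisphere is z-scored *within itself* across mask voxels (population
denominator), then flattened in the C-order mask scan into one row of the
N×V matrix (N = 2 × subjects; rows sorted by subject, left before right).
Standardizing per hemisphere, rather than per voxel across subjects,
removes the global left/right difference in mean volumetry so classifiers
must use the spatial pattern, not the offset.

This choice has a measurable side effect worth knowing: subtracting a row's
mean converts a localized deficit (say, 20 of 500 voxels lowered in left
hemispheres) into a small *uniform raise* of the remaining 480 voxels of
those rows. That compensatory shift is a genuine, distributed side signal —
about `k·Δ/V` per null voxel — and prediction-optimal sparse models will
spend weights on it. Consequently the L1 classifier's support is an
unreliable localizer even on data with perfectly localized ground truth;
localization is the job of the all-relevant selector (below). This mirrors
the practical motivation for pairing a sparse classifier with Boruta.

## Laterality quotient

`LQ = (R − L)/(R + L)` per homologous voxel pair of *unstandardized*
volumes (z-scored data would break the ratio), bounded in [−1, 1], positive
rightward. Voxels with `R + L = 0` are undefined and stored as NaN —
mapping them to 0 would masquerade as perfect symmetry. The cohort-mean map
averages over the maps in which a voxel is defined.

## Permutation TFCE test

The univariate arm tests `LQ = 0` per voxel with a one-sample t statistic
(n−1 denominator) and enhances the t map with threshold-free cluster
enhancement,

    TFCE(v) = ∫₀^{h_v} e(h)^E · h^H dh,

where `e(h)` is the extent of the connected component containing v among
voxels with statistic ≥ h. Defaults follow the standard volumetric choice:
E = 0.5, H = 2, 26-connectivity, 100 integration steps with `dh =
max(stat)/100`. The integral is discretized at *midpoint* heights
`h_k = (k − ½)·dh`; the midpoint rule keeps the error of smooth closed
forms below 0.01% at 100 steps, where a right-endpoint sum errs by ~1.5%.
Two engines implement the same discretization: a numba union-find kernel
that activates voxels in descending order (used everywhere), and a
connected-component-labelling route via `scipy.ndimage` kept as an
independent in-package cross-check.

Family-wise error is controlled by sign flipping: under the symmetric null
each subject's map may appear with either sign, so the null distribution of
the image-wide maximum TFCE score is built from random ±1 reweightings
(`p = (1 + #{max ≥ obs})/(1 + n_perm)`, never zero). When `2^n ≤ n_perm`
the full enumeration replaces sampling and p-values are exact multiples of
`2^{−n}`. Positive and negative tails are enhanced separately and
Bonferroni-combined for two-sided inference. The permutation stream is
seeded; identical `(seed, n_perm)` give identical p maps. Empirical FWE on
200 null cohorts sits inside the exact binomial 95% band around the nominal
0.05 (computed by the acceptance suite, not assumed).

## Low-dimensional arm

All rows are embedded jointly into two dimensions with UMAP (15 neighbors,
min_dist 0.1, Euclidean, fixed seed, single-threaded for determinism — all
exposed, since no canonical values exist for this application), then a
linear SVM (C = 1) is cross-validated on the coordinates with 5 folds × 5
repetitions, stratified by side. Per-fold accuracy and per-class precision
are recorded; embedding spread per side is compared with a variance-ratio
F-test (two-sided p at (n_R−1, n_L−1) df), and score sets from two runs
with an independent two-sample t-test (pooled variance; two 25-fold reports
compare on 48 df).

Folds are *not* grouped by subject by default, matching the common tooling
default. Note the consequence: when the two hemispheres of a subject are
nearly identical (strong shared subject-level variability), ungrouped CV
can anti-learn — the near-twin of each test row sits in training with the
opposite label — and push accuracy below chance. The `groups=` /
`group_by_subject=` options keep each subject's rows in one fold; the
chance-level test of the z-scoring rationale uses this leakage-safe
grouping. The embedding is fit on all rows before CV (fit-within-fold is a
caller-side variation, out of scope for the defaults).

## High-dimensional arm

The "LASSO classifier" is L1-penalized least squares on side labels encoded
−1/+1 with classification by the sign of the linear score (an L1-logistic
variant is selectable). The penalty grid spans 50 log-spaced values from
the smallest penalty that zeroes all weights down four decades. Within each
training fold the penalty is chosen by inner 3-fold accuracy under the
one-standard-error rule — the sparsest model statistically tied with the
best — which collapses to the plain argmax when folds agree and to the
empty model on pure noise. The final weight map is refit on all rows at the
log-median of the fold-selected penalties. Outer CV: 3 folds, 1 repetition,
stratified by side.

## All-relevant selection

Boruta: each iteration appends a freshly shuffled shadow copy of every
feature still in the model, fits a 200-tree random forest (depth-unlimited,
mean-decrease-in-impurity importances, seeded), and scores a hit for every
undecided feature whose importance beats the *maximum* shadow importance.
From iteration 5 onward, hit counts are tested two-sidedly against
Binomial(n, ½) at α = 0.01 with Bonferroni correction over the features
still under test; significantly-above confirms, significantly-below rejects
(rejected features leave the model). The loop stops early when nothing is
undecided. Tentative features are excluded from the selection mask unless
`resolve_tentative` promotes those whose median importance beats the median
shadow maximum. For very large V a `prescreen` mask (e.g. a dilated sparse-
classifier support) can bound the candidate set; off by default.

Note the Bonferroni arithmetic sets a floor on useful iteration counts: with
V features under test, a perfect hit streak first reaches significance at
`n ≈ log2(2V/α)` iterations (~18 for V = 500, α = 0.01), so `max_iter`
below ~20 cannot confirm anything at that scale.

## Map comparison

Dice similarity `DSC = 2|A∩B|/(|A|+|B|)`; two empty maps give 0 with a
warning so sweep curves stay plottable. The threshold sweep compares a
candidate map against directional binary maps `LQ ≥ t` (rightward) or
`LQ ≤ −t` (leftward) over a default grid of 0.02 to 0.60 in steps of 0.02 —
a decade-coarser grid cannot resolve peaks within the |LQ| ≤ 1 range.
Cluster summaries use 26-connected components with size and centroid,
plus per-component overlap fractions against any integer label volume
(no atlas is bundled).

## Subgroups

`split_by` divides the matrix by sex or handedness (right vs non-right,
pooling left and ambidextrous), keeping both hemispheres of a subject
together, excluding missing/"unknown" values with a logged count, and
refusing groups under 5 subjects. Each group is processed with identical
seeds and settings (embedding refit per group), and Boruta masks are
compared across groups with DSC. Group order does not affect results. No
between-group size matching is applied by default.

## Synthetic cohorts

The generator emulates VBM-like gray-matter maps on a per-hemisphere grid:

- a smooth bilateral template (Gaussian-blurred white noise, σ = 1.5
  voxels, values ≈ 0.3–0.8 on the tissue-fraction scale);
- a smooth subject-level field (sd `subject_sd`, default 0.05) *shared by
  both sides* — this is what makes a subject's two hemispheres near-twins;
- planted axis-aligned regions, each with a side and an effect δ: the
  hemisphere opposite the effect is scaled by `(1−δ)/(1+δ)`, which makes
  the noise-free voxel-wise LQ in the region *exactly* δ (closed-form
  ground truth, recorded in a truth record with voxel coordinates);
- independent voxel noise per side (sd `noise_sd`, default 0.05);
- an optional global side offset (the z-scoring rationale condition);
- `side_spread_ratio` ≥ 1 multiplying the right hemisphere's subject-level
  deviation (emulating larger right-hemisphere variability);
- optional group modulation of δ by a participants column;
- negative values clipped to zero.

Participants tables draw sex ≈ 55/45 F/M and handedness ≈ 80/17/3
right/left/ambidextrous, the typical composition of unselected young-adult
cohorts. What the generator does *not* emulate: cortical anatomy, the
spatial covariance of real segmentation output, registration error, or any
preprocessing chain — so passing tests demonstrate correctness and
calibration of the statistics on smooth random fields, not performance on
real morphometry.

## Problem sizes used by the test suite and acceptance script

Chosen once as desk-scale study conditions: recovery cohorts with 200
subjects, V = 500 (hemisphere grid 10×10×5), 20 planted voxels at a
per-voxel standardized side difference ≈ 1 (δ = 0.07 on the default
scales); FWE calibration on 200 cohorts of 20 subjects, ~200 mask voxels,
500 permutations; low-dimensional cohorts with 60 subjects and ~35% of
voxels covered by broad mixed-direction asymmetries plus spread ratio 2;
crossover cohorts with 40 subjects mixing δ ∈ {0.04, 0.05} and
{0.18, 0.20} regions.

## Known limitations

- The sparse classifier's support is not a localization map (see the
  standardization section); its job is the accuracy estimate.
- Ungrouped CV matches common tooling defaults but is leakage-prone on
  strongly paired data; grouping is one flag away.
- TFCE parameters are the volumetric defaults; surface data or very
  different smoothness would need retuning.
- UMAP determinism holds for fixed seed and library version; coordinates
  are not comparable across versions.
- The generator's planted blocks are axis-aligned and its noise white;
  none of the spatial-autocorrelation subtleties of real VBM residuals are
  represented.
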