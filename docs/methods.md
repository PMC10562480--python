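# Methods

## Habitat segmentation

Each MR sequence is treated independently within its own ROI (the T1 and
FLAIR ROIs are segmented separately and may differ). ROI intensities are
mapped to [0, 1] by `(v - min)/(max - min)`; a constant ROI raises an error
rather than producing an arbitrary split. A two-component univariate Gaussian
mixture is fitted by EM (scikit-learn), initialized by k-means with 5 restarts
and a fixed seed so results are reproducible; components are unconstrained in
variance by default (`equal_variance=True` switches to a shared variance).
The low/high threshold is the average of the two component means. Scaled
values strictly above the threshold are HIGH; values exactly at the threshold
go to LOW. If the fitted means are closer than `separation_tol` (default
1e-3) the ROI is reported as unimodal instead of being split at noise. Fits
require at least 20 ROI pixels (configurable).

Because the rescaling is linear and the GMM operates on the scaled values,
any affine transform of the raw intensities (gain/offset changes) leaves all
four masks unchanged; this is tested.

## Centroid maps

The grid (default 8 px; 8 mm at the 1 mm isotropic spacing assumed after
preprocessing) is anchored at the top-left corner of each habitat mask's
bounding box. Anchoring at the bounding box rather than the image origin makes
centroids equivariant under translation of the habitat without requiring
whole-image registration; the property is tested for shifts by grid multiples.
Each cell containing habitat pixels emits their center of mass in mm
(index × spacing); centroids are not snapped to the pixel lattice, and a
(cell, habitat) pair emits at most one point.

## Minimum spanning tree features

The MST is computed over the complete Euclidean graph on a habitat's
centroids with Kruskal's algorithm; equal-weight edges are ordered
lexicographically by vertex index, so a fixed point set always yields the
same edge set (equal-weight trees share the total weight but not the weight
multiset, and the features depend on the multiset — determinism matters).
The seven branch-length statistics use population (1/n) moments, exactly as
defined, not sample-corrected: mean, median (midpoint of the two central
values for even n), SD, skewness, kurtosis in the non-excess convention
(large normal samples → 3), the max/min ratio, and disorder = SD/mean.
With all branch lengths equal the SD is 0 and skewness/kurtosis are defined
as 0. A habitat with fewer than two centroids has no tree; its seven features
are recorded as missing (NaN), imputed later by the classifier harness, never
silently zeroed.

## Graph run-length matrix

All habitats' centroids form one labeled point set, triangulated with
scipy's Delaunay (Qhull). Qhull's deterministic handling of cocircular
degeneracies means a fixed input always yields the same edge set; collinear
or sub-triangle inputs raise a degenerate-geometry error. Edge types
enumerate the 10 unordered label pairs: the 4 same-label types first in label
order, then the 6 mixed pairs lexicographically.

A run is counted per (initial node, edge type): its length is the maximum
number of consecutive type-t edges along any simple path starting at the
node, found by depth-first search and capped at `l_max` (default 10, ample
for these sparse per-type subgraphs). The total run count n_r therefore
equals the number of (node, incident edge type) pairs, a conservation law the
tests check. The optional circular window of radius R mm centres on the
initial node: the first edge of a run always counts, and every node beyond
the first neighbor must lie strictly within R. This rule keeps every
(node, type) pair contributing exactly one run at any radius, and as R → 0
all runs shrink monotonically to length 1 (LPE → 1), which is also tested.
The window is unbounded by default (runs span the whole ROI).

Global features normalize by n_r; per-type SPE(t)/LPE(t) restrict the sums
to edge type t and normalize by n_r(t) — the only reading that produces 10
distinct per-type values. Types with no runs yield missing per-type features
(e.g. every type involving an absent habitat).

## Classifier harness

Stratified k-fold CV (default 5) with shuffling under a fixed seed. Within
each training fold: missing features are imputed by the training-fold median
(columns that are all-missing in the fold fall back to 0); class imbalance is
removed by resampling the minority class with replacement up to the majority
count (seeded); then a random forest (default 10,000 trees, reducible for
speed) is fitted. Probabilities are pooled out-of-fold before ROC analysis —
one curve over all subjects rather than per-fold averaging. AUC is the
trapezoidal area under the threshold-sweep ROC, which equals the pairwise
Mann–Whitney statistic with ties counted 1/2 (tested exactly). The operating
cutoff maximizes sensitivity + specificity, ties resolved toward the smallest
threshold; accuracy comes from the confusion matrix at that cutoff. MAE is
the mean absolute difference between predicted probability and the 0/1 label.
Gini importances come from a forest refit on the full imputed table.
Dichotomization rules: survival > 12 months → class 1; score > cohort
median → class 1 (a score equal to the median goes down).

## Synthetic phantoms

Phantoms emulate preprocessed 2D slices: 1 mm isotropic spacing, an
elliptical ROI shared by both sequences, in-ROI intensities drawn from a
two-component Gaussian mixture per sequence, and background noise at 10% of
the low-component mean (masks exclude it; it only makes image files
realistic). The defaults — 128 px image, semi-axes 52 × 40 px (~6500 ROI
pixels), means 100/200 (T1) and 90/180 (FLAIR) with SD 10, `high_fraction`
0.2, 4 blobs — were chosen so the 8-px grid yields ~150 cells and the
spatial-clustering knob has a detectable geometric consequence: at
`clustering = 0` the ~1300 high pixels cover essentially every grid cell,
while at 0.8 the scattered remainder falls to ~1.3 pixels per cell, thinning
and displacing the high-habitat centroids and carving the low habitat around
the blobs. Blob centers are rejection-sampled inside the ROI with a minimum
separation of one blob radius (relaxed after 500 tries so generation cannot
fail); exact high-pixel counts are `round(high_fraction · n_roi)`, so the
mixture weight is exact rather than binomially noisy. Ground-truth component
masks ride along on the generated slice pair for recovery scoring.

Cohorts shift `clustering` (and optionally `high_fraction`) for class-1
subjects; per-subject seeds are spawned from the cohort seed, so cohorts are
bit-reproducible. With no class effect the classes are exchangeable by
construction and the pipeline's cross-validated AUC stays near 0.5 (tested
within [0.35, 0.65]).

What the phantoms do **not** emulate: 3D volumes, bias fields, registration
error, scanner-to-scanner intensity variation, irregular tumor shapes, or
correlated T1/FLAIR habitat geometry. Passing the planted-effect test shows
the pipeline detects spatial clustering of an intensity component under ideal
mixture assumptions — it does not certify performance on clinical images.

## Problem sizes and numerical choices

The end-to-end acceptance checks use 30 + 30 phantom cohorts with the forest
reduced to 1,000 trees, which keeps a full planted + null evaluation around
half a minute on one CPU while leaving the CV machinery untouched. Oracle
tests compare the MST against exhaustive spanning-tree enumeration on ≤ 7
points and the GRLM against an independent full simple-path enumerator on
≤ 12-node random labeled graphs, both exactly. Formula fixtures are asserted
to 1e-12. Degenerate inputs (constant ROI, unimodal ROI, < 2 centroids,
collinear centroid sets, empty run matrices, single-class labels) raise typed
errors at the API level; the pipeline converts per-subject failures into
logged missing rows so one bad subject never aborts a cohort.

## Known limitations

* Analysis is strictly 2D (one slice per subject), by design.
* The per-node-type run-counting convention and the unbounded default window
  are documented choices; alternative conventions (per incident edge, finite
  windows) are configurable but change feature scales.
* Immune-signature scores are accepted as precomputed per-subject scalars and
  dichotomized at the median; computing them from expression data is out of
  scope.
* The random-forest harness reports pooled out-of-fold ROC metrics; per-fold
  averaging would give slightly different numbers.
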