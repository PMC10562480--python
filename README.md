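# habitatgraph

Graph-based spatial-heterogeneity features for tumor MRI habitats.

Intensity heterogeneity inside a tumor reflects coexisting sub-regions
("habitats") with different physiology. `habitatgraph` quantifies not just the
abundance of such habitats but their **spatial proximity structure** on a 2D MR
slice, and evaluates whether those spatial features discriminate binary
clinical outcomes (e.g. 12-month survival status, immune-signature status).
It is aimed at quantitative-imaging researchers who have co-registered
post-contrast T1-weighted and T2-FLAIR slices with tumor ROI masks — or who
want to study the method itself on the built-in synthetic phantoms.

## Method

1. **Habitats.** Per sequence, ROI intensities are rescaled to [0, 1] by a
   linear map and fitted with a two-component Gaussian mixture; the ROI is
   split at the threshold (μ₁ + μ₂)/2 into low/high habitats, giving four
   binary masks: T1-high, T1-low, T2-high, T2-low.
2. **Centroid maps.** An 8-pixel grid (8 mm at 1 mm spacing) is overlaid on
   each habitat mask; every grid cell containing habitat pixels emits the
   center of mass of those pixels.
3. **MST features (28).** Per habitat, a Euclidean minimum spanning tree is
   built over the centroids and seven branch-length statistics of its weight
   set W = {w₁…w_n} are computed: mean f_µ, median, population SD f_σ,
   skewness, (non-excess) kurtosis, max/min ratio f_r, and disorder f_σ/f_µ.
4. **GRLM features (24).** Centroids of all four habitats are combined and
   Delaunay-triangulated; each graph edge gets one of 10 edge types (unordered
   habitat-label pairs). The graph run-length matrix G(t, l) counts, per
   initial node and edge type t, the longest run of l consecutive type-t edges
   along a simple path (optionally truncated by a circular window). Features:
   short/long path emphasis SPE = (1/n_r) Σ G(t,l)/l² and
   LPE = (1/n_r) Σ G(t,l)·l², edge-type and path-length nonuniformity
   ETN/PLN, plus per-type SPE(t) and LPE(t) for the 10 types.
5. **Evaluation.** A random forest (default 10,000 trees) under stratified
   5-fold cross-validation with class-proportional resampling; ROC/AUC on
   pooled out-of-fold probabilities, the cutoff maximizing
   sensitivity + specificity, accuracy ACC = (TP+TN)/(TP+FN+TN+FP) at that
   cutoff, MAE, and Gini feature importances.

The synthetic-phantom module generates elliptical tumor ROIs whose in-ROI
intensities follow a known two-component mixture, with a `clustering` knob
that moves high-intensity pixels from uniform scatter into compact blobs —
a ground-truth spatial effect the feature pipeline should detect.

## Worked example

```python
import habitatgraph as hg
import pandas as pd

params = hg.PhantomParams(clustering=0.8, seed=3)
subject = hg.generate_phantom(params, subject_id="demo")
masks = hg.make_habitat_masks(subject, seed=0)
mst = hg.subject_mst_features(masks)
grlm = hg.subject_grlm_features(masks)
```

prints (via the accompanying `print` statements):

```
T1 GMM threshold: 0.514
T1-high MST mean branch length: 6.70 mm
T1-high MST disorder:           0.180
global SPE=0.249  LPE=40.569  ETN=169.1  PLN=208.7
```

The threshold 0.514 is the average of the two fitted component means on the
[0, 1] scale; 6.70 mm is the mean MST branch length between T1-high centroids
(shorter than the ~7.0 mm of an unclustered phantom, because compact blobs
pull centroids together); SPE near 0.25 with large LPE/ETN/PLN says most runs
are short but a few same-type chains are long and run counts concentrate on
few edge types. A planted-effect cohort is classified end to end:

```python
cohort = hg.generate_cohort(hg.CohortSpec(n_per_class=10, clustering_effect=0.8, seed=5))
rows, labels = [], []
cfg = hg.PipelineConfig(rf_trees=500)
for sp, label in cohort:
    features, _ = hg.subject_features(sp, cfg)
    rows.append(features); labels.append(label)
report = hg.evaluate_features(pd.DataFrame(rows), labels, n_trees=500, k=5, seed=5)
```

```
cross-validated AUC: 1.000  accuracy: 1.000
top feature: t2high_mean
```

The clustering effect of 0.8 is strong enough that the forest separates the
classes perfectly, led by the mean MST branch length of the T2-high habitat.

## Command line

```bash
habitatgraph simulate --config cohort.yaml --out cohort/ --seed 1
habitatgraph run --manifest cohort/manifest.csv --out results/ --seed 1
habitatgraph classify --features results/features.csv --labels labels.csv \
    --outcome months --rule threshold-12-months --out report.json
```

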