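# Methods

This note documents the model implemented by `patchconn`, the main
parameter choices and their rationale, and the package's known limitations.

## Overview

`patchconn` builds, per subject, a structural brain-connectivity network
from a single T1-weighted volume in template space, classifies subjects
into three diagnostic groups (AD / MCI / NC) from nodal network features,
and explains the classification with additive Shapley attributions that are
finally mapped onto named atlas regions. Because real diagnostic T1 cohorts
are access-controlled, the package ships a synthetic-cohort generator with
planted, class-specific atrophy so the whole chain can be validated against
a known ground truth.

## Stages

### 1. Parcellation

The template brain mask is divided at the mid-sagittal plane (the central
x index; for odd x-dimensions the central plane belongs to neither
hemisphere). Each hemisphere is tiled by a regular grid of fixed-size
rectangular patches — default 10 × 15 × 20 mm, i.e. 3,000 voxels at 1 mm —
anchored at the minimal corner of the hemisphere mask's bounding box. Boxes
that would cross the midline or extend past the grid are dropped; of the
rest, a box is retained iff at least 10% of its voxels are brain (the exact
10% boundary is kept). Patch ids run left hemisphere first, then right, in
raster order, and are shared by every subject.

On the MNI152 2009a 1 mm brain mask (197 × 233 × 189) this convention
yields 773 patches (382 left, 391 right). Published patch counts for this
kind of tiling depend on unstated details (mask variant, tiling origin,
cropping rule) and an odd total cannot arise from two hemispheres carrying
an equal number of patches, so the count itself is reported, not asserted.

### 2. Connectome

The link weight between two patches is the absolute Pearson correlation of
their voxel-intensity vectors, within subject. Absolute values make
mirrored left/right intensity patterns connect alike. Weights below 0.3 are
removed as noise (weights exactly at the threshold survive). A patch vector
with zero variance correlates 0 with everything rather than raising, so one
degenerate patch cannot abort a subject.

### 3. Graph metrics

Three complementary nodal centralities are computed per patch:

- **strength** — sum of incident edge weights (local);
- **betweenness** — fraction of all-pairs shortest paths through the node,
  normalized by (P−1)(P−2)/2, with edge distance 1/w so stronger
  correlations are shorter (dynamic);
- **eigenvector centrality** — the dominant eigenvector of the weighted
  adjacency, sign-fixed, clipped at 0 and unit-normalized (global).

Stacking the three metrics for every subject gives the M × 3P feature
matrix (columns metric-major, named `strength_0007` etc.).

### 4. Classification

Repeated stratified k-fold cross-validation (defaults 10 folds × 50
repeats, configurable) over five fixed-hyperparameter model families:
random forest (500 trees), RBF-kernel SVM, XGBoost (200 trees, depth 4),
Gaussian naive Bayes, and L2 logistic regression. SVM/NB/LR sit behind a
train-fold StandardScaler inside a Pipeline so no test-fold statistics leak
into the model. Performance is summarised as per-repeat accuracy (mean of
fold accuracies), per-class one-vs-rest AUC, and a pooled confusion matrix;
agreement between two classifiers is the per-class Pearson correlation of
their probability scores.

### 5. Feature selection

Inside every fold, a 200-tree random forest is fitted on the training rows
and each feature's Mean Decrease Accuracy (MDA) is measured as the drop in
out-of-bag accuracy under B = 30 seeded within-column permutations. Two
filters follow: (1) keep features whose MDA lies strictly above the fold's
95th percentile; (2) keep those whose accuracy dropped in significantly
more than half of the B rounds by an exact one-sided binomial test against
Bin(B, 1/2) at α = 0.05.

In practice, on the synthetic cohorts the two-stage filter usually keeps
nothing: with a few dozen highly correlated network features, a redundant
forest rarely changes ≥ 20 of 30 out-of-bag predictions when a single
column is permuted, so the binomial filter's success counts stay below its
critical value. The designed fallback — the top 10 features by MDA — then
feeds the downstream stages, and planted-effect recovery succeeds through
it. The binomial construction (trials = permutation rounds, success = any
positive drop, null p = 1/2) is one plausible operationalisation and is
isolated in `binomial_filter` so alternatives can be swapped in.

A smaller forest (100 trees) is retrained on the selected columns for the
explanation stage. Everything is fold-local: no test row influences the
selection.

### 6. Explainability

Every test subject of every fold receives an additive attribution:
baseline E[f(x)] (mean model output over a seeded background subsample of
the training rows, default 16 rows) plus one term per selected feature,
summing exactly to the subject's own score. For the multiclass model, f is
the probability of the subject's true class (configurable to the predicted
class); three one-vs-rest forests, trained on the same selected features,
are explained on their positive-class probability.

Shapley values are interventional: v(S) = mean over background of
f(x_S, z_~S). They are computed by **exact exhaustive coalition
enumeration** whenever the model has ≤ 13 features — which the selection
stage guarantees here — and by a seeded antithetic permutation-sampling
estimator otherwise. Both routes satisfy efficiency exactly. Exact
enumeration was chosen over path-dependent tree-specific algorithms because
it is a few dozen lines that can be verified against the classical
factorial formula to machine precision, and is exact for any model, not
only trees; its cost (2^d coalitions × background rows, batched through a
fast forest evaluator) is acceptable precisely because d is small.

Mean |φ| across explanations gives a global ranking and per-class rankings
(class rankings use only subjects the one-vs-rest model classified
correctly). Rankings are compared by Spearman correlation, with an exact
permutation p-value when ten or fewer features are shared.

### 7. Atlas report

Each patch is assigned the modal atlas label over its in-mask voxels
(ties toward the smallest label id; patches with no labeled voxel are
flagged unlabeled). The top-k ranked features expand into a (feature,
metric, patch, region) table plus a deduplicated region list in
first-appearance order — the clinically readable output.

## Synthetic cohort

The generator emulates post-preprocessed data: skull-stripped, intensity
normalized, all subjects sharing one template mask (an ellipsoid with a
one-voxel mid-sagittal fissure, default grid 60 × 45 × 60 at 1 mm, which
yields 15 patches / 45 features). All subjects share a deterministic
baseline intensity pattern — low-frequency cosines on scales comparable to
the patch size plus a radial term, amplitudes ≈ 0.03–0.06 around mean 1.0 —
so patch pairs span both sides of the 0.3 link threshold. For a subject of
class c, the baseline is multiplied by (1 − effect_size) inside that
class's affected patches, then smoothed Gaussian noise (FWHM 2 mm, marginal
sd = noise_sd after rescaling) is added, clipped at 0 and masked.

A uniform multiplicative change is invisible to Pearson correlation on its
own; the planted signal reaches the network through signal-to-noise
attenuation — scaling a patch down by 30% against fixed additive noise
lowers its correlations with other patches. The baseline amplitudes and
noise correlation scale were therefore chosen, at design time, so the
default effect_size 0.3 / noise_sd 0.05 regime gives detectable but
imperfect separation (reference run: three-class accuracy ≈ 0.6 against a
chance level of 1/3, AD one-vs-rest AUC ≈ 0.95). These defaults are the
frozen study conditions.

Reference conditions (also run by `scripts/acceptance.py`): 60 subjects per
class, five affected patches for AD ({0,2,4,6,8}) and five for MCI
({1,3,5,7,9}), 5 repeats × 10 folds, random forest only.

## Determinism

All randomness descends from a single integer seed: per-subject generator
streams, per-repeat fold seeds, per-fold selection seeds, per-fold
explanation backgrounds. A rerun with the same config writes byte-identical
fold assignments, feature matrices and selections.

## Problem sizes and runtime

Desk-scale defaults (15 patches, 180 subjects, 5 × 10 CV): the full
pipeline runs in single-digit minutes on one CPU. The dominant costs are
the per-fold MDA permutations (~2.5 s/fold, computed with cached per-tree
leaf tables so only trees that split on the permuted feature are
re-applied) and the exact Shapley enumeration (linear in background size;
the default of 16 background rows keeps it ~6 s/fold).

## Limitations

- The generator does not simulate scanner artifacts, bias fields,
  registration error, geometric shrinkage, or longitudinal change.
- The binomial selection filter is conservative on correlated features (see
  above); the fallback path is then what feeds explanation.
- Betweenness relies on exact shortest-path ties being absent, which holds
  almost surely for continuous weights.
- Exact Shapley enumeration is limited to 13 features; beyond that the
  seeded sampling estimator introduces Monte-Carlo error (efficiency still
  holds exactly).
- The atlas report assigns each patch a single modal region; patches
  straddling region boundaries are summarised by their dominant label only
  (the full histogram is kept in `region_map`).
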