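# Methods

`octraman` implements a discrimination analysis for five skin-cell types —
HaCaT keratinocytes, A431 squamous-cell carcinoma (SCC), BCC-1/KMC
basal-cell carcinoma (BCC), primary melanocytes and A375 melanoma — from
two modalities: cellular-resolution full-field OCT volumes (morphology and
backscattering intensity) and Raman spectra (molecular composition).  The
original cell measurements are not publicly deposited, so the package ships
a synthetic-data generator that reproduces the *statistical structure* the
analysis relies on, and every pipeline stage is validated against analytic
phantoms and generator ground truth.

## Synthetic OCT phantoms

A cell is a star-convex body: a sphere of radius `r` whose radius function
carries `k` Gaussian bumps ("protrusions") of amplitude `a` at directions
drawn uniformly on the unit sphere:

    r(u) = r + a · min( Σᵢ exp(−∠(u, uᵢ)² / 2σ²), 2.5 ),   σ = 0.3 rad.

The cap at 2.5·a bounds the maximal radius independently of the random
directions, which makes grid sizing and the fits-inside-grid precondition
deterministic.  The body is voxelised on an anisotropic grid (defaults
0.45 µm lateral, 0.2 µm axial — the instrument's pixel pitch); interior
voxels draw `N(µ_in, σ_in)` and background `N(0, σ_bg)`, clipped at zero.
Slide reflections are additive uniform z-planes.

Per-class defaults (means ± SD; `synth/profiles.py`) encode the reported
qualitative structure, since no quantitative effect sizes are published:

| class      | r (µm)    | k        | a (µm)      | µ_in     | σ_in     |
|------------|-----------|----------|-------------|----------|----------|
| HaCaT      | 6.4 ± 0.5 | 3 ± 1.5  | 0.40 ± 0.25 | 80 ± 7   | 22 ± 2.5 |
| melanocyte | 6.7 ± 0.5 | 3 ± 1.5  | 0.40 ± 0.25 | 140 ± 8  | 20 ± 2.5 |
| SCC        | 6.2 ± 0.5 | 9 ± 2.5  | 1.6 ± 0.45  | 115 ± 7  | 10 ± 1.5 |
| BCC        | 7.8 ± 0.6 | 9 ± 2.5  | 1.6 ± 0.45  | 112 ± 7  | 10 ± 1.5 |
| melanoma   | 6.5 ± 0.5 | 10 ± 2.5 | 1.7 ± 0.45  | 105 ± 7  | 11 ± 1.5 |

These realise: cancer rougher and less compact than normal; SCC/BCC
brighter than HaCaT; melanocytes brighter than melanoma; normal cells with
larger internal-intensity SD; BCC larger than HaCaT/SCC.  The within-class
spreads are deliberately broad enough that volume and compactness overlap
between classes — mirroring the observation that shape features
discriminate cancer lines poorly — while the intensity features separate
cleanly.  What passing tests show is therefore that the *pipeline recovers
a class structure of this kind when it is present*; they do not certify
effect sizes in real cells, speckle statistics, refractive-index physics or
organelle substructure, none of which are modelled.

## Synthetic Raman spectra

A spectrum is Σ Gaussian band peaks (FWHM 12 cm⁻¹, twice the instrument's
6 cm⁻¹ resolution) + a cubic fluorescence baseline in the reduced
coordinate `u = (w−350)/1750`, multiplied by a detector roll-off factor
(linear from 1 at 1350 cm⁻¹ to 0.2 at 2100 cm⁻¹, standing in for the sharp
germanium quantum-efficiency drop), plus `N(0, noise_sd · s)` noise where
`s` is a per-class variability scale (HaCaT 4, melanocyte 3, cancer lines
1 — normal-cell spectra are reported 2–5× more variable).  Shared band
centres sit at 780, 935, 1000, 1290, 1450, 1660 cm⁻¹; the three cancer
lines add partially disjoint bands (SCC 890/1340, BCC 850/1240, melanoma
970/1120/1550 cm⁻¹).  A sample is swept at 12 points: replicates share
sample-level peak heights (relative SD `0.04·s`) and differ in noise.  The
default grid is 351 + 3k cm⁻¹ so the 600 and 2100 cm⁻¹ analysis-window
edges are grid points.

## Segmentation

Four steps.  (1) *Crop*: slices whose mean exceeds `median + c·robust SD`
(robust SD = 1.4826·MAD, default c = 5) of the slice means are removed as
slide reflections; an optional `trim_tail` flag additionally drops slices
below the deepest cell-bearing slice — off by default so cropping touches
exactly the flagged planes.  (2) *Filter*: separable Gaussian, σ = 2 px
in-plane and 4.5 px axially, truncated at 4σ, kernel renormalised to unit
sum, reflective boundaries; the implementation is checked against a dense
brute-force convolution oracle to 1e-10.  (3) *Binarise*: global Mean
threshold (T = image mean, strict `>`); marker-controlled watershed on the
negated Euclidean distance transform (physical units; markers are distance
maxima ≥ 5 µm apart, with tied plateau voxels merged into one marker by
connected labelling); per-slice 3×3 erosion (border voxels eroded).
(4) *Label*: the watershed partition restricted to the eroded foreground,
26-connected, components under `min_object_voxels` (default 500 ≈ 20 µm³)
discarded, ids sorted by decreasing size.  Erosion follows watershed,
before labelling, per the listed operation order.  Mosaicking of stage
tiles is rigid with intensity averaging in overlaps; no registration.

## Features

Per cell, on the *unfiltered* volume and the hole-filled object mask:

* volume `V` = voxel count × voxel volume;
* surface area `A` from a marching-cubes iso-surface at 0.5.  The binary
  mask is first Gaussian-smoothed with width `0.49·max(spacing)` (≈0.22 µm
  at the default pitch): without this the voxel staircase inflates a 10 µm
  sphere's area by ~14%; with it the sphere is within ~2.4% and a cube
  within ~5% of the analytic values.  Because the width is tied to the
  spacing, `A` scales exactly as s² under uniform rescaling and sphere
  compactness is nearly resolution-independent (≈0.93) rather than
  converging to 1 from below;
* compactness `C = 36πV²/A³` (1 for a sphere; sphericity `C^{1/3}`);
* RMS surface roughness `SR` (Rq): the top-surface height map takes the
  shallowest foreground voxel per lateral column; SR is the population RMS
  deviation about the mean height (Ra, the mean-absolute variant, is an
  option).  A hemisphere of radius R gives the closed form `R/(3√2)`;
* mean intensity `AI` and population SD `IS` inside the mask.

Intensity statistics use the raw volume because smoothing biases the SD
downward.  All features are mask-restricted, hence invariant to anything
added outside the object.

## Raman preprocessing

Reference (objective) subtraction with clipping at zero; fluorescence
removal by asymmetric least squares (λ = 1e5, p = 0.01, ≤10 iterations:
minimise `Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)²`, `wᵢ = p` above the baseline), with
iterative polynomial fitting (degree 5) as an alternative; replicate
averaging per sample; cropping to 600–2100 cm⁻¹; linear-interpolation
resampling to a common grid and row-wise none/vector/area normalisation
(default none).  No roll-off correction is attempted — the rolled-off
region stays in the analysis window as acquired.  On noise-free input a
second ALS pass changes the corrected spectrum by <1% RMS; with noise, the
clip-at-zero step rectifies residuals into a small pedestal (~0.5 a.u.)
that a second pass removes, so exact idempotence is a clean-input property.

## Classification

Base learners with fixed settings: LDA (pooled covariance, pseudo-inverse
when singular, delta/gamma regularisers 0 — implemented in-package because
boosting needs sample-weight support, with weighted class means/covariance
reducing to ordinary LDA at uniform weights); 1-NN (Euclidean, equal
weights, *no* standardisation — deliberately scale-sensitive; exact ties
resolve to the lowest training index via a brute-force neighbour search);
CART (Gini, ≤ n−1 splits, min leaf 1, all variables per split).  Ensembles:
bagging (bootstrap + majority vote; one learner without bootstrap *is* the
base learner), boosting (adaptive reweighting, learning rate 1; refused for
KNN), random subspace (feature subsets of dimension ⌈p/2⌉ by default,
majority vote, no resampling).  The six attempted pairings are
boosting/bagging/subspace+LDA, subspace+KNN, boosting/bagging+TREE, with 30
learners by default (sizes are unpublished).

Evaluation is stratified 10-fold cross-validation (stratified because
per-class counts are small; if the smallest class has fewer members than
folds, the fold count degrades to that size), pooled accuracy, confusion
matrix and per-sample fold assignments, deterministic per seed.  Features
are ranked by single-feature CV accuracy (ties to the lower column index)
to form the "1&2"/"1&2&3" subsets.  Four tasks: cancer vs normal, HaCaT vs
melanocyte, melanoma vs keratinocyte-lineage cancers, BCC vs SCC.

Fusion of the modalities into a five-class call is not specified by the
source analysis beyond its narrative; the package's reading is a two-stage
scheme sharing CV folds: stage 1 calls cancer/normal on OCT features
(bagged trees); predicted normals split HaCaT/melanocyte on OCT features;
predicted cancers split melanoma/BCC/SCC on the Raman matrix (1-NN).

## Significance reporting

Per feature and class pair, a two-sided Welch t-test (Mann–Whitney U
optional) mapped to three marks: `O` for p < 0.001, `TRIANGLE` for
0.001 ≤ p < 0.05, `X` for p ≥ 0.05 — half-open intervals, so the
boundaries land on the weaker mark.  Two constant identical samples give
p = 1 (no evidence of difference).  No multiple-testing correction by
default; Holm adjustment over the grid is available.

## Problem sizes and numerical choices

The classification experiments use populations of 50 cells/class; the test
suite checks the cancer-vs-normal recovery criterion over 10 seeds and the
feature-subset comparison over 20, and the reproduction script averages
over 5 population seeds, 3 segmentation seeds and 5 Raman seeds — sizes at
which the reported statistics are stable to well under a percentage point
while a full run stays in the minutes range on one CPU.  Classification
features are measured on generator ground-truth masks; segmentation
accuracy is validated separately (object-count recovery), because the mean
threshold deliberately over-includes a halo around cells (the erosion step
exists to counter this) and per-voxel mask fidelity is not the analysis'
quantity of interest.  Degenerate inputs error early and descriptively:
constant volumes (no mean-threshold foreground), cells exceeding the grid
(named axis), empty crop windows, single-class training sets.  One-voxel-
thick objects fall back to voxel-face surface area with a warning.

## Known limitations

* No speckle/coherence physics, melanin absorption or organelle
  substructure in the phantoms; intensity classes are Gaussian blobs.
* The star-convex shape model cannot produce concave or touching-lobed
  cells; watershed splitting is exercised on constructed overlapping
  spheres instead.
* Compactness carries the smoothing estimator's ~7% systematic offset for
  spheres; comparisons across cells (same estimator) are unaffected.
* The fusion scheme is one reading of an unspecified procedure; its
  five-class accuracy on synthetic data should not be compared to any
  published figure.
* Accuracies near 100% on the synthetic population reflect the generator's
  clean class structure, not expected real-cell performance.
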