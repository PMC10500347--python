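# octraman

Discrimination of five skin-cell types — HaCaT keratinocytes, squamous-cell
carcinoma (SCC/A431), basal-cell carcinoma (BCC), primary melanocytes and
melanoma (A375) — from two complementary modalities:

* **cellular-resolution OCT volumes**: 3D segmentation (Gaussian filtering,
  mean auto-threshold, watershed, erosion, 3D labelling) and five per-cell
  features — volume *V*, compactness *C = 36πV²/A³*, RMS surface roughness
  *SR*, mean intensity *AI* and internal intensity SD *IS*;
* **Raman spectra**: fluorescence-baseline removal (asymmetric least
  squares), replicate averaging, 600–2100 cm⁻¹ windowing and full-spectrum
  feature matrices.

Both feed an ensemble machine-learning protocol — LDA / 1-NN / decision
trees wrapped in bagging, boosting and random-subspace architectures with
stratified 10-fold cross-validation — over four discrimination tasks
(cancer vs normal, HaCaT vs melanocyte, melanoma vs keratinocyte-lineage
cancers, BCC vs SCC), plus a two-stage OCT+Raman fusion for the five-class
problem and a per-feature class-pair significance grid (O: p < 0.001,
△: p < 0.05, X: otherwise).

Because the underlying cell measurements are not publicly deposited, the
package includes a first-class synthetic generator (`octraman.synth`)
producing OCT phantoms (star-convex cells with protrusion bumps, slide
reflection planes) and Raman spectra (band peaks + fluorescence baseline +
detector roll-off, class-dependent variability) with ground truth, so the
entire pipeline is testable end to end.  The model and all defaults are
documented in [docs/methods.md](docs/methods.md).

Intended users: researchers in label-free optical cytology who want a
tested, scriptable reference implementation of this analysis, or a
scaffold to run it on their own TIFF stacks and spectra.

## Worked example

```python
from octraman.classify import TASKS, best_per_classifier, run_task
from octraman.experiments import oct_design_matrix, population_feature_table

features = population_feature_table(n_per_class=20, seed=1)   # 100 cells
X, y = oct_design_matrix(features)                            # V C SR AI IS
grid = run_task(X, y, TASKS["cancer_vs_normal"],
                pairings=(("bagging", "TREE"), ("subspace", "KNN")),
                feature_subsets=("V", "AI", "IS", "1&2&3", "ALL"), seed=1)
print(best_per_classifier(grid)[["classifier", "ensemble",
                                 "feature_subset", "accuracy"]])
```

prints

```
classifier ensemble feature_subset  accuracy
       KNN subspace          1&2&3      1.00
      TREE  bagging             IS      0.99
```

i.e. on a 20-cells-per-class synthetic population the best
classifier+ensemble pairing separates cancer from normal cells essentially
perfectly once the intensity features are in play, while volume alone
reaches only ~0.63 — the generator encodes exactly this contrast between
intensity/roughness and shape features.  The scripts in `examples/` walk
through each capability (phantom generation, segmentation + features,
Raman preprocessing, task grids, significance reporting) and print a short
interpretation with their numbers.

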