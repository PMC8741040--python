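# nucdhl

Nuclear morphometry and deep hybrid learning for classifying cancerous vs
normal nuclei in lamin-stained fluorescence micrographs.

Nuclear enlargement and shape change are classical hallmarks of malignancy,
and the nuclear lamina (lamin A / lamin B) outlines the nucleus in
immunofluorescence images of tissue. `nucdhl` implements a dual-pipeline
classifier of single-nucleus micrographs for this setting, together with a
calibrated synthetic data generator that makes the whole system testable
without access to clinical images:

* **Pipeline 1 — morphometry.** Each nucleus is modelled as an ellipse with
  semi-axes *a* ≥ *b* and focal half-distance *c* = √(*a*² − *b*²). Eight
  shape descriptors are computed analytically — area π*ab*, perimeter
  (Ramanujan's second approximation), circularity 4π·area/perimeter²,
  eccentricity *c*/*a*, foci distance 2*c*, loop length 2*a* + 2*c*, maximum
  curvature *a*/*b*² and its equal-area normalisation (*a*/*b*²)·√(*ab*).
  The table is standard-scaled, PCA-reduced (95% retained variance) and
  classified by adaptive boosting under stratified 5-fold cross-validation,
  with random-forest and decision-tree comparators.
* **Pipeline 2 — deep hybrid learning (DHL).** Pre-processed images
  (HSV-value segmentation with a sensitivity factor, elliptical-kernel
  morphological closing, unsharp-mask sharpening, grayscaling, background
  zeroing, normalisation) feed a 21-layer convolutional encoder built from
  Incept blocks (5×5 stride-2 entry, parallel 3×3/5×5 branches) and Squeeze
  blocks (1×1 entry, parallel 1×1/3×3 branches), all Leaky-ReLU with L2
  penalty and dropout 0.20. The flattened features go to a gradient-boosted
  tree (or random-forest) head instead of a dense readout.
* **Fusion.** Per sample, the verdict is
  `Decision = max(p_adaboost, p_deep)`, thresholded at 0.5.
* **Synthetic benchmark.** A generator draws ellipse geometries whose
  population moments (area, eccentricity, and — through a solved copula
  correlation — perimeter) match published group statistics of normal vs
  ovarian-cancer nuclei for lamin A/B-stained tissue, renders them as
  rim-plus-fill confocal-style micrographs, and emits index-aligned images,
  descriptor tables and ground-truth geometries.

The CNN engine (im2col convolutions, Adam, cross-entropy, hand-written
gradients verified against finite differences) is implemented on NumPy
within the package.

## Worked example

```bash
python examples/02_calibrated_populations.py
```

prints (seed 1):

```
normal lamin A (n = 338):
  area          generated   22.273   published   23.470 +- 0.713 (SEM)
  perimeter     generated   17.499   published   17.820 +- 0.303 (SEM)
  eccentricity  generated    0.722   published    0.707 +- 0.012 (SEM)
cancer lamin A (n = 393):
  area          generated   48.788   published   51.620 +- 1.153 (SEM)
  perimeter     generated   27.257   published   27.590 +- 0.333 (SEM)
  eccentricity  generated    0.805   published    0.788 +- 0.008 (SEM)
eccentricity shift normal -> cancer: 11.6% (the published means imply about 12%)
```

Each generated sample mean lies within the ±3 SEM band of the published
group statistic at the inferred study size, and the ~12% eccentricity shift
between groups is reproduced. `examples/` holds one short script per
capability (single-nucleus morphometry, population calibration, rendering +
pre-processing, pipeline 1, the deep-hybrid run, fusion + orchestration);
each prints the numbers it computes and a line on what they mean.

A `nucdhl` command-line tool wraps the same library calls
(`simulate`, `morphometry`, `stats`, `preprocess`, `train`, `evaluate`,
`compare`, `run`); `nucdhl run --profile desk --out runs/demo` executes the
whole experiment and writes manifests, per-split predictions and a model
comparison report into the run directory.

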