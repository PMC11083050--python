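# Methods

## Problem and pipeline

`milletspec` implements a nondestructive cultivar-identification analysis
for proso millet (*Panicum miliaceum* L.) seeds imaged with a push-broom
NIR hyperspectral camera (254 bands, ~900–1700 nm). The study design it
follows scans ten cultivars, ten replicate scans each, fifty seeds per scan
arranged in a non-touching 5×10 grid — 5000 seeds in total. The processing
chain is:

1. **Reflectance calibration.** Raw digital numbers R₀ are corrected
   frame-wise with a white (~99% PTFE target) and a dark (capped-lens)
   reference: R = (R₀ − R_d)/(R_w − R_d). Pixel-bands with R_w = R_d have no
   dynamic range; they are set to 0 and counted in the cube's provenance
   rather than raising, since isolated dead pixels should not abort a scan.
   Values slightly outside [0, 1] are retained — clipping would bias the SNV
   statistics downstream. Note the method reports reflectance *relative to
   the white target*: with a 0.99-reflectance target the calibrated values
   are true reflectance divided by 0.99.
2. **Two-mask segmentation.** A background mask thresholds the band nearest
   1050 nm (Otsu by default; the threshold value is not part of the
   protocol, only the band is), then 8-connected component labelling
   numbers the seeds 1..n in raster order of first pixel; components under
   `min_area = 10 px` are dropped as specks. The second mask is the
   per-seed equality test on the label image.
3. **Mean-spectrum extraction.** Each seed's spectrum is the arithmetic
   per-band mean over its pixels, collected into a table annotated with
   cultivar, scan id, seed index and pixel count.
4. **Preprocessing**, in fixed order: trim 6 leading + 15 trailing bands
   (254 → 233, removing detector roll-off), maximum normalization,
   Savitzky–Golay smoothing (27-point window, quadratic; "width 27" is read
   as 27 points, not 27 nm), and SNV standardization. SNV uses the sample
   standard deviation (n−1). Savitzky–Golay edges use polynomial
   interpolation over the truncated edge window rather than padding; the
   trim step removes most edge bands anyway.
5. **Features.** Either the full 233 preprocessed bands, the first k = 2
   mean-centred principal components, or k wavebands chosen by sequential
   forward selection (SFS). PCA is refitted on the training rows inside
   every evaluation repeat so no test information leaks into the features.
   Component signs are fixed by forcing each loading's largest-magnitude
   element positive, making results fully deterministic. SFS greedily adds
   the band maximising mean stratified 5-fold CV accuracy (ties to the
   lowest band index) and reports the elimination percentage
   100·(1 − k/n), e.g. 98.03% for 5 of 254 bands.
6. **Classification.** Five fixed-hyperparameter models: LDA; RBF-SVM with
   σ = 1, C = 1 under the convention γ = 1/(2σ²) = 0.5 (one-vs-one
   multiclass); kNN with 5 neighbours, Euclidean metric; random forest with
   Gini criterion (500 trees — the tree count is a free choice and is
   logged); gradient tree boosting with learning rate 0.1, 1000 estimators,
   max depth 10. Evaluation is five repeats of a stratified 80/20 holdout;
   the headline number is mean ± sd (sample sd) of test accuracy over
   repeats, and per-class precision/recall/F1 come from test predictions
   pooled across the five repeats. Classes never predicted are reported
   with precision 0 and an explicit flag rather than NaN.

## Synthetic scan generator

The instrument data behind the original study are not deposited, so the
package ships a first-class simulator whose defaults *are* the study
conditions: 10 cultivars × 10 scans × 50 seeds, 254 bands, seeds in a 5×10
non-touching grid on a dark (reflectance 0.05) stage.

* **Wavelength axis.** 254 linearly spaced band centres fixed by requiring
  the 233 retained bands after the 6/15 trim to span 900.17–1673.58 nm (the
  extreme wavebands a band-selection table can produce); the instrument's
  exact axis is unpublished.
* **Cultivar signatures.** All cultivars share Gaussian absorption dips at
  920, 1200, 1400 and 1700 nm (water, carbohydrate and protein overtone
  bands) superimposed on a smooth base curve. Cultivars differ in base
  level, spectral tilt and leading-dip depth, each spread by at least the
  `separation` parameter (default 0.01 reflectance units — strong enough
  that cultivars are distinguishable, weak enough that raw level alone does
  not trivially separate them before scatter correction). `separation=0`
  collapses all cultivars to one curve.
* **Scene.** Seeds are axis-aligned ellipses (semi-axes 4×3 px, ±10% size
  and ±1 px centre jitter) on a 68×108 px frame; the configuration is
  rejected up front if jittered seeds could violate the 1 px clearance. Seed
  shape is irrelevant to mean spectra, so no more realistic morphology is
  attempted.
* **Acquisition model.** Raw DN = illumination × reflectance + dark current
  + N(0, noise_sd²). The default illumination (~3000 DN) has a 15% radial
  falloff and a broad spectral bell; the dark offset (~100 DN) a mild
  along-sensor gradient — enough structure that skipping calibration
  visibly distorts spectra. Sensor noise defaults to 5 DN; the real
  sensor's bit depth and noise statistics are unpublished, so these are
  stated choices, not inferred facts. Raw values stay floating-point in
  memory and are quantized to uint16 only when written to ENVI, where the
  gain makes quantization loss negligible.
* **Variability.** Seed level: multiplicative N(1, 0.01²) plus a small
  additive offset (seed size / packing); pixel level: multiplicative
  N(1, 0.02²) per pixel (within-seed texture).
* **Determinism.** Every output is a pure function of configuration and
  seed; dataset generation derives one sub-seed per scan from a seed
  sequence, and re-runs are byte-identical (manifest paths are stored
  relative to the manifest for this reason).

What the simulator does **not** emulate: specular highlights, touching
seeds, moisture kinetics, wavelength-correlated (1/f or fixed-pattern)
noise, or chemically mechanistic spectra. Passing tests therefore show that
the pipeline's machinery is correct and recovers planted structure — not
that real proso millet cultivars are separable at any particular accuracy.
The original study's real-data accuracies are not reproduction targets for
the same reason.

## Numerical and statistical choices

* The calibration round-trip check treats the stated 3·(noise_sd/√n_px)
  band-wise bound as a per-band 3σ standard error. Across 50 seeds × 254
  bands a literal "every band" reading fails with high probability for pure
  Gaussian noise, so the test asserts the 3σ bound on >99% of bands and a
  hard 5σ cap on all of them.
* Chance-level behaviour is checked at 10 balanced classes with a binomial
  tolerance around 10%.
* Problem sizes: the full-scale benchmark renders all 100 scans in memory
  (~20 s), extracts 5000 spectra, and evaluates the five classifiers on 2
  PCA features over five repeats; smaller examples and unit tests use 2–5
  cultivars with 1–4 scans.

## Known limitations

* SFS with the gradient-boosting default estimator over all 233 bands is
  computationally heavy; in practice a cheaper scorer (kNN, LDA) is the
  pragmatic choice for exploration, and the estimator is pluggable for
  exactly this reason.
* The ENVI reader supports the BIL/BIP/BSQ dialects with little-endian
  data and the data types the pipeline writes (uint8/16, int16/32,
  float32/64); it is not a general vendor-format reader.
* Whether the original analysis thresholded reflectance or raw intensity at
  1050 nm, and whether its reference frames were full frames or averaged
  lines, is unstated; this implementation thresholds calibrated reflectance
  and uses frame-wise references.
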