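"""Benchmark classifiers on PCA features by repeated stratified holdout.

Uses a reduced synthetic dataset (5 cultivars x 4 scans = 1000 seeds) and
fast classifiers so the example runs in seconds; the full-scale bench with
all five classifiers is what tests/ and the pipeline `run` execute.
"""

from milletspec import (
    ClassifierSpec,
    evaluate_repeated_split,
    fit_pca,
    pca_feature_extractor,
    preprocess_pipeline,
    simulate_and_extract,
)

table = simulate_and_extract(n_cultivars=5, scans_per_cultivar=4,
                             separation=0.01, noise_sd=5.0, rng_seed=3)
pre = preprocess_pipeline(table)

pca = fit_pca(pre.spectra, k=2)
evr = pca.explained_variance_ratio
print(f"PC1 explains {100*evr[0]:.1f}% of variance, PC2 {100*evr[1]:.1f}% "
      f"(cumulative {100*evr.sum():.1f}%)")

specs = [ClassifierSpec.default(n) for n in ("LDA", "SVM", "kNN", "RF")]
reports = evaluate_repeated_split(
    pre.spectra, pre.labels, specs,
    test_fraction=0.2, repeats=5, base_seed=3,
    feature_extractor=pca_feature_extractor(2),  # PCA refitted inside each split
)

print(f"\n{'classifier':<6} {'train %':>16} {'test %':>16}")
for name, rep in reports.items():
    print(f"{name:<6} {rep.train_mean:>10.2f} +/- {rep.train_sd:<4.2f}"
          f"{rep.test_mean:>10.2f} +/- {rep.test_sd:<4.2f}")
print("\nMean +/- sd over 5 stratified 80/20 splits; test accuracy is the")
print("fraction of held-out seeds whose cultivar is predicted correctly.")
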