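"""Select the most discriminative wavebands with sequential forward selection.

SFS greedily adds the band that most improves cross-validated accuracy,
showing how many of the 254 instrument bands a cheaper multispectral sensor
would actually need.  A small dataset and a kNN scorer keep this example
fast; the estimator is pluggable (the gradient-boosting spec is the
default at full scale).
"""

from milletspec import ClassifierSpec, preprocess_pipeline, sfs_select, simulate_and_extract

table = simulate_and_extract(n_cultivars=4, scans_per_cultivar=2,
                             separation=0.015, noise_sd=5.0, rng_seed=9)
pre = preprocess_pipeline(table)

k = 5
res = sfs_select(pre, k=k, estimator=ClassifierSpec.default("kNN"), cv_folds=5, rng_seed=9)

print(f"selected {k} of {res.n_total_bands} wavebands (nm): {res.format_wavelengths()}")
print(f"feature elimination: {res.elimination_percent:.2f}%")
print("cv accuracy after each addition: "
      + ", ".join(f"{s:.3f}" for s in res.cv_score_trace))
print("\nThe trace shows accuracy saturating after a few bands: most of the")
print("cultivar signal is concentrated at a handful of absorption features.")
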