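"""Render one synthetic hyperspectral seed scan and write it as an ENVI pair.

A scan is a 5x10 grid of non-touching elliptical seeds of one cultivar on a
dark stage, imaged over 254 NIR bands with a spatial illumination field,
dark current and sensor noise baked into the raw digital numbers.
"""

from pathlib import Path

from milletspec import SceneConfig, default_wavelength_axis, make_signatures, render_scan, write_envi

axis = default_wavelength_axis()
signatures = make_signatures(n_cultivars=10, wavelength_axis=axis, separation=0.01, rng_seed=7)
sig = signatures[0]

raw, white, dark, truth = render_scan(sig, SceneConfig(rng_seed=7), noise_sd=5.0)

out = Path("scratch/example_scan")
out.mkdir(parents=True, exist_ok=True)
for scan, stem in ((raw, "scan"), (white, "white"), (dark, "dark")):
    hdr, cube = write_envi(scan, out / stem)
    print(f"wrote {cube} ({scan.lines}x{scan.samples}x{scan.bands})")

print(f"cultivar: {sig.cultivar_name}")
print(f"wavelengths: {axis[0]:.2f}-{axis[-1]:.2f} nm in {axis.size} bands")
print(f"seeds rendered: {truth.n_seeds} (labels 1..{truth.labels.max()})")
print("Raw digital numbers mix illumination, dark current and reflectance;")
print("the truth label map is what segmentation should recover after calibration.")
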