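import numpy as np
import pytest

from milletspec import (
    RawScan,
    ReferenceFrames,
    SceneConfig,
    calibrate,
    default_wavelength_axis,
    generate_dataset,
    make_signatures,
    render_scan,
)
from milletspec.synthetic import default_dark_offset, default_illumination


class TestWavelengthAxis:
    def test_retained_bands_span_the_trimmed_range(self, axis):
        assert axis.size == 254
        assert axis[6] == pytest.approx(900.17)
        assert axis[254 - 15 - 1] == pytest.approx(1673.58)
        assert np.all(np.diff(axis) > 0)


class TestSignatures:
    def test_ten_cultivars_on_default_axis(self, signatures):
        assert len(signatures) == 10
        assert all(s.base_curve.size == 254 for s in signatures)
        assert len({s.cultivar_name for s in signatures}) == 10

    def test_zero_separation_collapses_to_identical_curves(self, axis):
        sigs = make_signatures(4, axis, separation=0.0, rng_seed=5)
        for s in sigs[1:]:
            np.testing.assert_array_equal(s.base_curve, sigs[0].base_curve)
            assert s.dip_depths == sigs[0].dip_depths

    def test_same_seed_gives_bit_identical_signatures(self, axis):
        a = make_signatures(6, axis, separation=0.02, rng_seed=9)
        b = make_signatures(6, axis, separation=0.02, rng_seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.base_curve, y.base_curve)
            assert x.dip_depths == y.dip_depths

    def test_levels_and_lead_dip_depths_spread_by_separation(self, axis):
        sep = 0.012
        sigs = make_signatures(5, axis, separation=sep, rng_seed=2)
        levels = sorted(float(s.base_curve.mean()) for s in sigs)
        assert all(b - a >= sep - 1e-12 for a, b in zip(levels, levels[1:]))
        depths = sorted(s.dip_depths[0] for s in sigs)
        assert all(b - a >= sep - 1e-12 for a, b in zip(depths, depths[1:]))

    def test_non_increasing_axis_rejected_naming_index(self):
        bad = np.array([900.0, 910.0, 905.0, 920.0])
        with pytest.raises(ValueError, match="index 2"):
            make_signatures(3, bad, rng_seed=0)

    def test_expected_spectrum_has_absorption_dips(self, signatures):
        sig = signatures[0]
        spec = sig.expected_spectrum()
        assert np.all(spec > 0)
        for centre in (920.0, 1400.0):
            i = int(np.argmin(np.abs(sig.wavelengths - centre)))
            assert spec[i] < sig.base_curve[i]


class TestRenderScan:
    def test_truth_map_has_fifty_distinct_labels(self, noise_free_scan):
        _, _, _, truth = noise_free_scan
        labels = np.unique(truth.labels)
        assert truth.n_seeds == 50
        assert labels.min() == 0 and labels.max() == 50
        assert labels.size == 51

    def test_identity_acquisition_reproduces_reflectance(self, signatures):
        raw, _, _, truth = render_scan(
            signatures[1], SceneConfig(rng_seed=4),
            illumination_profile=1.0, dark_offset=0.0, noise_sd=0.0,
        )
        # raw DN = 1 * reflectance + 0, so seed pixels carry the seed spectra
        seed_px = raw.cube[truth.labels > 0]
        assert seed_px.min() > 0.2
        stage_px = raw.cube[truth.labels == 0]
        np.testing.assert_allclose(stage_px, 0.05)

    def test_same_scene_seed_renders_identically(self, signatures):
        a = render_scan(signatures[2], SceneConfig(rng_seed=8), noise_sd=3.0)
        b = render_scan(signatures[2], SceneConfig(rng_seed=8), noise_sd=3.0)
        for x, y in zip(a[:3], b[:3]):
            np.testing.assert_array_equal(x.cube, y.cube)
        np.testing.assert_array_equal(a[3].labels, b[3].labels)

    def test_white_frame_encodes_its_target_level(self, signatures):
        """Calibrating the 0.99-target white frame against an ideal (perfect
        reflector) white recovers 0.99; against itself it is exactly 1."""
        scene = SceneConfig(rng_seed=6)
        sig = signatures[0]
        illum = default_illumination(scene, sig.wavelengths)
        dark = default_dark_offset(scene, sig.wavelengths.size)
        _, white, dark_frame, _ = render_scan(sig, scene, illum, dark, noise_sd=0.0)
        ideal_white = RawScan(illum * 1.0 + dark, sig.wavelengths, {})
        vs_ideal = calibrate(white, ReferenceFrames(white=ideal_white, dark=dark_frame))
        np.testing.assert_allclose(vs_ideal.cube, 0.99, rtol=1e-9)
        vs_self = calibrate(white, ReferenceFrames(white=white, dark=dark_frame))
        np.testing.assert_allclose(vs_self.cube, 1.0, rtol=1e-9)

    def test_overlapping_seed_layout_rejected_before_rendering(self):
        with pytest.raises(ValueError, match="overlap"):
            SceneConfig(n_rows=5, n_cols=10, image_lines=30, image_samples=40)

    def test_negative_noise_rejected(self, signatures):
        with pytest.raises(ValueError, match="noise_sd"):
            render_scan(signatures[0], SceneConfig(), noise_sd=-1.0)

    def test_calibration_roundtrip_recovers_expected_spectrum(self, axis):
        """With only sensor noise, the calibrated per-seed mean tracks the
        signature's expected spectrum within ~3 standard errors."""
        sigs = make_signatures(2, axis, separation=0.0, rng_seed=1,
                               seed_level_sd=0.0, pixel_level_sd=0.0)
        sig = sigs[0]
        scene = SceneConfig(rng_seed=12)
        gain, noise_dn = 2000.0, 4.0
        raw, _, _, truth = render_scan(sig, scene, illumination_profile=gain,
                                       dark_offset=0.0, noise_sd=noise_dn)
        white = RawScan(np.full_like(raw.cube, gain * 0.99), axis, {})
        dark = RawScan(np.zeros_like(raw.cube), axis, {})
        refl = calibrate(raw, ReferenceFrames(white=white, dark=dark))
        # calibration reports reflectance relative to the 0.99 white target
        expected = sig.expected_spectrum() / 0.99
        sd_refl = noise_dn / (gain * 0.99)
        for lab in range(1, truth.n_seeds + 1):
            px = refl.cube[truth.labels == lab]
            tol = 3.0 * sd_refl / np.sqrt(px.shape[0])
            dev = np.abs(px.mean(axis=0) - expected)
            # 3-sigma bound per band; across 50 seeds x 254 bands a few
            # Gaussian excursions past 3 sigma are expected, none past 5
            assert np.mean(dev <= tol) > 0.99
            assert dev.max() <= 5.0 * sd_refl / np.sqrt(px.shape[0])


class TestGenerateDataset:
    def test_small_dataset_counts_and_determinism(self, tmp_path):
        kwargs = dict(n_cultivars=2, scans_per_cultivar=1, rng_seed=21,
                      separation=0.01, noise_sd=2.0)
        m1 = generate_dataset(tmp_path / "a", **kwargs)
        assert len(m1.scans) == 2
        assert m1.total_seeds == 100
        assert all((tmp_path / "a" / f).exists() for f in ("manifest.csv", "seeds.csv"))
        for rec in m1.scans:
            assert (tmp_path / "a" / f"{rec.scan_id}.hdr").exists()

        generate_dataset(tmp_path / "b", **kwargs)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            a, b = (tmp_path / "a" / name), (tmp_path / "b" / name)
            if name.endswith((".raw", ".csv")):
                assert a.read_bytes() == b.read_bytes(), name

    def test_default_design_totals_5000_seeds(self):
        # 10 cultivars x 10 scans x 50 seeds, asserted on the scene contract
        scene = SceneConfig()
        assert 10 * 10 * scene.n_seeds == 5000


class TestClassStructure:
    def test_between_cultivar_distance_exceeds_within(self, axis):
        from milletspec import simulate_and_extract

        table = simulate_and_extract(n_cultivars=3, scans_per_cultivar=2,
                                     separation=0.02, noise_sd=2.0, rng_seed=5)
        labels = table.labels
        centroids = {c: table.spectra[labels == c].mean(axis=0) for c in np.unique(labels)}
        within = max(
            np.linalg.norm(table.spectra[labels == c] - centroids[c], axis=1).mean()
            for c in centroids
        )
        cs = list(centroids)
        between = min(
            np.linalg.norm(centroids[a] - centroids[b])
            for i, a in enumerate(cs) for b in cs[i + 1:]
        )
        assert between > within
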