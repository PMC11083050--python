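"""Synthetic NIR hyperspectral seed scans with known ground truth.

The study design this package targets — ten proso millet cultivars, ten
scans per cultivar, fifty seeds per scan laid out in a non-touching 5x10
grid on a dark stage, 254 bands across ~900-1700 nm — used instrument data
that is not publicly deposited, so this module generates scenes with the
same statistical structure and full ground truth:

* each cultivar has a smooth reflectance signature: a shared curve shape
  with per-cultivar level/slope and Gaussian absorption dips at the NIR
  overtone bands near 920, 1200, 1400 and 1700 nm (water, carbohydrate and
  protein absorptions);
* seeds are rendered as axis-aligned ellipses with small per-seed size and
  position jitter, never touching;
* raw digital numbers are `illumination x reflectance + dark current +
  Gaussian sensor noise`, with matching white (~99% target) and dark
  reference frames, so reflectance calibration is genuinely exercised.

Every output is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .envi import RawScan, write_envi
from .segmentation import SeedLabelMap

__all__ = [
    "CultivarSignature",
    "SceneConfig",
    "TruthManifest",
    "ScanRecord",
    "default_wavelength_axis",
    "make_signatures",
    "render_scan",
    "generate_dataset",
    "DEFAULT_CULTIVAR_NAMES",
]

N_BANDS_DEFAULT = 254
# Band centres chosen so that after trimming 6 + 15 edge bands the retained
# 233 bands span exactly 900.17-1673.58 nm.
_RETAINED_FIRST_NM = 900.17
_RETAINED_LAST_NM = 1673.58
_TRIM_START, _TRIM_END = 6, 15

# NIR overtone absorption features typical of cereal grain reflectance.
DEFAULT_DIP_CENTERS_NM = (920.0, 1200.0, 1400.0, 1700.0)
DEFAULT_DIP_DEPTHS = (0.10, 0.08, 0.16, 0.12)
DEFAULT_DIP_WIDTHS_NM = (28.0, 45.0, 50.0, 60.0)

# The ten most popular US proso millet cultivars; used as default labels.
DEFAULT_CULTIVAR_NAMES = (
    "Cerise", "Cope", "Earlybird", "Huntsman", "Minco",
    "Plateau", "Rise", "Snowbird", "Sunrise", "Sunup",
)


def default_wavelength_axis(n_bands: int = N_BANDS_DEFAULT) -> np.ndarray:
    """Linearly spaced band centres emulating the instrument's spectral axis.

    The spacing is fixed by requiring the 233 bands that survive the standard
    6/15 edge trim to span 900.17-1673.58 nm; the full axis then runs from
    ~880 to ~1724 nm over ``n_bands`` bands.
    """
    if n_bands <= _TRIM_START + _TRIM_END + 1:
        raise ValueError(f"n_bands={n_bands} too small for the 6/15 trimmed-span convention")
    step = (_RETAINED_LAST_NM - _RETAINED_FIRST_NM) / (n_bands - _TRIM_START - _TRIM_END - 1)
    start = _RETAINED_FIRST_NM - _TRIM_START * step
    return start + step * np.arange(n_bands)


@dataclass
class CultivarSignature:
    """Expected reflectance model for one cultivar.

    The per-seed expected spectrum is ``base_curve`` minus Gaussian dips of
    the given centres/depths/widths.  ``seed_level_sd`` scales seed-to-seed
    variability (multiplicative level plus additive offset, mimicking seed
    size and packing); ``pixel_level_sd`` scales within-seed pixel-to-pixel
    level variation.  All reflectances are unitless fractions.
    """

    cultivar_name: str
    wavelengths: np.ndarray
    base_curve: np.ndarray
    dip_centers_nm: tuple = DEFAULT_DIP_CENTERS_NM
    dip_depths: tuple = DEFAULT_DIP_DEPTHS
    dip_widths_nm: tuple = DEFAULT_DIP_WIDTHS_NM
    seed_level_sd: float = 0.01
    pixel_level_sd: float = 0.02

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.base_curve = np.asarray(self.base_curve, dtype=float)
        if self.base_curve.shape != self.wavelengths.shape:
            raise ValueError("base_curve and wavelengths must have equal length")
        if np.any(self.base_curve <= 0) or np.any(self.base_curve > 1):
            raise ValueError(f"{self.cultivar_name}: base_curve values must lie in (0, 1]")
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        for c in self.dip_centers_nm:
            if not (lo <= c <= hi):
                raise ValueError(
                    f"{self.cultivar_name}: dip centre {c} nm outside axis span [{lo:.2f}, {hi:.2f}]"
                )
        if len(self.dip_centers_nm) != len(self.dip_depths) or len(self.dip_depths) != len(
            self.dip_widths_nm
        ):
            raise ValueError("dip centres, depths and widths must have equal length")
        if any(d < 0 for d in self.dip_depths) or any(w < 0 for w in self.dip_widths_nm):
            raise ValueError("dip depths and widths must be non-negative")
        if self.seed_level_sd < 0 or self.pixel_level_sd < 0:
            raise ValueError("variability standard deviations must be non-negative")
        if np.any(self.expected_spectrum() <= 0):
            raise ValueError(
                f"{self.cultivar_name}: dips drive expected reflectance to or below 0"
            )

    def expected_spectrum(self) -> np.ndarray:
        """Base curve with the absorption dips applied (per-seed expectation)."""
        spec = self.base_curve.copy()
        for c, d, w in zip(self.dip_centers_nm, self.dip_depths, self.dip_widths_nm):
            if w > 0 and d > 0:
                spec -= d * np.exp(-0.5 * ((self.wavelengths - c) / w) ** 2)
        return spec


def make_signatures(
    n_cultivars: int,
    wavelength_axis: np.ndarray | None = None,
    separation: float = 0.01,
    rng_seed: int = 0,
    names: tuple[str, ...] | None = None,
    seed_level_sd: float = 0.01,
    pixel_level_sd: float = 0.02,
) -> list[CultivarSignature]:
    """Build ``n_cultivars`` signatures sharing dip locations.

    Cultivars share the absorption-dip wavelengths but differ in base
    reflectance level, spectral slope and the depth of the leading dip, each
    spread by at least ``separation`` (unitless reflectance) between
    neighbouring cultivars.  With ``separation=0`` all signatures collapse to
    the same curve.  Deterministic in ``rng_seed``.
    """
    if n_cultivars < 2:
        raise ValueError(f"n_cultivars must be >= 2, got {n_cultivars}")
    axis = default_wavelength_axis() if wavelength_axis is None else np.asarray(wavelength_axis, float)
    diffs = np.diff(axis)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise ValueError(
            f"wavelength axis must be strictly increasing; index {bad + 1} "
            f"({axis[bad + 1]:g} nm) does not exceed index {bad} ({axis[bad]:g} nm)"
        )
    if separation < 0:
        raise ValueError("separation must be non-negative")

    rng = np.random.default_rng(rng_seed)
    centered = np.arange(n_cultivars) - (n_cultivars - 1) / 2.0
    levels = 0.55 + centered * separation
    # random tilt direction, amplitude tied to separation so separation=0 is degenerate
    slopes = rng.uniform(-1.0, 1.0, size=n_cultivars) * separation
    depth_offsets = (rng.permutation(n_cultivars) - (n_cultivars - 1) / 2.0) * separation

    t = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0  # [-1, 1]
    shared_shape = 0.03 * (1.0 - t**2)  # gentle broad hump common to all cultivars

    if names is None:
        if n_cultivars <= len(DEFAULT_CULTIVAR_NAMES):
            names = DEFAULT_CULTIVAR_NAMES[:n_cultivars]
        else:
            names = tuple(f"cultivar_{i:02d}" for i in range(n_cultivars))
    elif len(names) != n_cultivars:
        raise ValueError(f"got {len(names)} names for {n_cultivars} cultivars")

    signatures = []
    for i in range(n_cultivars):
        base = levels[i] + slopes[i] * t + shared_shape
        depths = np.array(DEFAULT_DIP_DEPTHS, dtype=float)
        depths[0] = max(depths[0] + depth_offsets[i], 0.0)
        signatures.append(
            CultivarSignature(
                cultivar_name=names[i],
                wavelengths=axis,
                base_curve=base,
                dip_depths=tuple(depths),
                seed_level_sd=seed_level_sd,
                pixel_level_sd=pixel_level_sd,
            )
        )
    return signatures


@dataclass
class SceneConfig:
    """Geometry of one simulated scan: a non-touching grid of elliptical seeds.

    Dimensions are pixels.  ``seed_axes_px`` are the nominal ellipse
    semi-axes (line, sample); per-seed jitter perturbs axes by up to
    ``axis_jitter`` (fraction) and centres by up to ``center_jitter_px``.
    The configuration is rejected at construction if the jittered seeds
    could not keep at least ``min_gap_px`` of clearance.
    """

    n_rows: int = 5
    n_cols: int = 10
    seed_axes_px: tuple[float, float] = (4.0, 3.0)
    image_lines: int = 68
    image_samples: int = 108
    stage_reflectance: float = 0.05
    rng_seed: int = 0
    axis_jitter: float = 0.10
    center_jitter_px: float = 1.0
    min_gap_px: int = 1

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.image_lines, self.image_samples) < 1:
            raise ValueError("grid and image dimensions must be positive")
        if self.seed_axes_px[0] <= 0 or self.seed_axes_px[1] <= 0:
            raise ValueError("seed semi-axes must be positive")
        if not (0 < self.stage_reflectance < 1):
            raise ValueError("stage_reflectance must be in (0, 1)")
        cell_h = self.image_lines / self.n_rows
        cell_w = self.image_samples / self.n_cols
        max_a = self.seed_axes_px[0] * (1 + self.axis_jitter)
        max_b = self.seed_axes_px[1] * (1 + self.axis_jitter)
        need_h = 2 * max_a + 2 * self.center_jitter_px + self.min_gap_px
        need_w = 2 * max_b + 2 * self.center_jitter_px + self.min_gap_px
        if need_h > cell_h or need_w > cell_w:
            raise ValueError(
                f"seeds would overlap: a {self.n_rows}x{self.n_cols} grid in a "
                f"{self.image_lines}x{self.image_samples} frame leaves cells of "
                f"{cell_h:.1f}x{cell_w:.1f} px but jittered seeds need "
                f"{need_h:.1f}x{need_w:.1f} px"
            )

    @property
    def n_seeds(self) -> int:
        return self.n_rows * self.n_cols


def _as_gain(profile, scene: SceneConfig, n_bands: int, what: str) -> np.ndarray:
    """Broadcast a scalar / 2-D / 3-D illumination or offset field to the cube shape."""
    shape = (scene.image_lines, scene.image_samples, n_bands)
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 0:
        return np.broadcast_to(arr, shape)
    if arr.ndim == 2:
        if arr.shape != shape[:2]:
            raise ValueError(f"{what} spatial shape {arr.shape} != frame {shape[:2]}")
        return np.broadcast_to(arr[:, :, None], shape)
    if arr.ndim == 3:
        if arr.shape != shape:
            raise ValueError(f"{what} shape {arr.shape} != cube {shape}")
        return arr
    raise ValueError(f"{what} must be scalar, 2-D or 3-D")


def default_illumination(scene: SceneConfig, wavelengths: np.ndarray, gain_dn: float = 3000.0) -> np.ndarray:
    """Halogen-lamp-like illumination field in digital numbers.

    Spatially a smooth radial falloff (~15% corner loss), spectrally a broad
    bell peaking mid-axis — enough structure that skipping calibration would
    visibly distort spectra.
    """
    rr = (np.arange(scene.image_lines) - scene.image_lines / 2) / (scene.image_lines / 2)
    cc = (np.arange(scene.image_samples) - scene.image_samples / 2) / (scene.image_samples / 2)
    radial2 = rr[:, None] ** 2 + cc[None, :] ** 2
    spatial = 1.0 - 0.15 * radial2 / 2.0
    t = (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0]) * 2 - 1
    spectral = 0.75 + 0.25 * (1 - t**2)
    return gain_dn * spatial[:, :, None] * spectral[None, None, :]


def default_dark_offset(scene: SceneConfig, n_bands: int, level_dn: float = 100.0) -> np.ndarray:
    """Dark-current offset with a mild along-sensor gradient, in digital numbers."""
    grad = 1.0 + 0.1 * np.linspace(-1, 1, scene.image_samples)
    return np.broadcast_to(level_dn * grad[None, :, None], (scene.image_lines, scene.image_samples, n_bands)).copy()


def _place_seeds(scene: SceneConfig, rng: np.random.Generator):
    """Jittered grid placement; returns per-seed (center_r, center_c, a, b)."""
    cell_h = scene.image_lines / scene.n_rows
    cell_w = scene.image_samples / scene.n_cols
    placements = []
    for r in range(scene.n_rows):
        for c in range(scene.n_cols):
            cr = (r + 0.5) * cell_h + rng.uniform(-scene.center_jitter_px, scene.center_jitter_px)
            cc = (c + 0.5) * cell_w + rng.uniform(-scene.center_jitter_px, scene.center_jitter_px)
            a = scene.seed_axes_px[0] * (1 + rng.uniform(-scene.axis_jitter, scene.axis_jitter))
            b = scene.seed_axes_px[1] * (1 + rng.uniform(-scene.axis_jitter, scene.axis_jitter))
            placements.append((cr, cc, a, b))
    return placements


def render_scan(
    signature: CultivarSignature,
    scene: SceneConfig | None = None,
    illumination_profile=None,
    dark_offset=None,
    noise_sd: float = 5.0,
) -> tuple[RawScan, RawScan, RawScan, SeedLabelMap]:
    """Render one scan plus its white and dark reference frames.

    Raw digital numbers follow ``illumination x reflectance + dark + noise``
    per pixel-band; the white frame images a 0.99-reflectance target under
    the same illumination, the dark frame is offset plus noise only.
    ``noise_sd`` is the additive Gaussian sensor noise in digital-number
    units (use 0 for a noise-free scene).  Returns ``(raw, white, dark,
    truth_labels)``; the truth map numbers seeds 1..n in grid raster order.
    Deterministic in ``scene.rng_seed``.
    """
    scene = SceneConfig() if scene is None else scene
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    wavelengths = signature.wavelengths
    n_bands = wavelengths.size
    rng = np.random.default_rng(scene.rng_seed)

    illum = (
        default_illumination(scene, wavelengths)
        if illumination_profile is None
        else _as_gain(illumination_profile, scene, n_bands, "illumination_profile")
    )
    dark = (
        default_dark_offset(scene, n_bands)
        if dark_offset is None
        else _as_gain(dark_offset, scene, n_bands, "dark_offset")
    )

    # ground-truth reflectance scene: dark stage + seeds
    refl = np.full((scene.image_lines, scene.image_samples, n_bands), scene.stage_reflectance)
    labels = np.zeros((scene.image_lines, scene.image_samples), dtype=np.int32)
    expected = signature.expected_spectrum()
    yy, xx = np.mgrid[0 : scene.image_lines, 0 : scene.image_samples]

    for idx, (cr, cc, a, b) in enumerate(_place_seeds(scene, rng), start=1):
        inside = ((yy - cr) / a) ** 2 + ((xx - cc) / b) ** 2 <= 1.0
        if not inside.any():
            raise ValueError(f"seed {idx} rasterized to zero pixels; enlarge seed_axes_px")
        level = 1.0 + rng.normal(0.0, signature.seed_level_sd)
        offset = rng.normal(0.0, signature.seed_level_sd / 2.0)
        seed_spec = np.clip(expected * level + offset, 1e-4, None)
        n_px = int(inside.sum())
        pix = 1.0 + rng.normal(0.0, signature.pixel_level_sd, size=n_px)
        refl[inside] = pix[:, None] * seed_spec[None, :]
        labels[inside] = idx

    def acquire(target_refl: np.ndarray) -> np.ndarray:
        dn = illum * target_refl + dark
        if noise_sd > 0:
            dn = dn + rng.normal(0.0, noise_sd, size=dn.shape)
        return np.clip(dn, 0.0, None)

    raw = RawScan(acquire(refl), wavelengths.copy(),
                  {"description": f"synthetic scan {signature.cultivar_name}"})
    white = RawScan(acquire(np.full_like(refl, 0.99)), wavelengths.copy(),
                    {"description": "synthetic white reference (0.99 target)"})
    dark_dn = dark.copy()
    if noise_sd > 0:
        dark_dn = dark_dn + rng.normal(0.0, noise_sd, size=dark_dn.shape)
    dark_frame = RawScan(np.clip(dark_dn, 0.0, None), wavelengths.copy(),
                         {"description": "synthetic dark reference"})
    truth = SeedLabelMap(labels=labels, n_seeds=scene.n_seeds)
    return raw, white, dark_frame, truth


@dataclass
class ScanRecord:
    scan_id: str
    cultivar: str
    header_path: str
    white_header_path: str
    dark_header_path: str
    seed_centroids: list = field(default_factory=list)  # (line, sample) per seed
    seed_pixel_counts: list = field(default_factory=list)


@dataclass
class TruthManifest:
    """Ground truth for a generated dataset: one record per scan."""

    scans: list

    @property
    def total_seeds(self) -> int:
        return sum(len(rec.seed_pixel_counts) for rec in self.scans)

    def to_csv(self, manifest_path: str | Path, seeds_path: str | Path | None = None) -> None:
        manifest_path = Path(manifest_path)

        def rel(p: str) -> str:
            # paths relative to the manifest keep re-runs byte-identical
            try:
                return str(Path(p).relative_to(manifest_path.parent.resolve()))
            except ValueError:
                return str(p)

        rows = [
            {
                "scan_id": r.scan_id,
                "cultivar": r.cultivar,
                "header_path": rel(r.header_path),
                "white_header_path": rel(r.white_header_path),
                "dark_header_path": rel(r.dark_header_path),
                "n_seeds": len(r.seed_pixel_counts),
            }
            for r in self.scans
        ]
        pd.DataFrame(rows).to_csv(manifest_path, index=False)
        if seeds_path is not None:
            seed_rows = []
            for r in self.scans:
                for i, ((cl, cs), npx) in enumerate(zip(r.seed_centroids, r.seed_pixel_counts), 1):
                    seed_rows.append(
                        {"scan_id": r.scan_id, "seed_index": i,
                         "centroid_line": cl, "centroid_sample": cs, "pixel_count": npx}
                    )
            pd.DataFrame(seed_rows).to_csv(seeds_path, index=False)

    @classmethod
    def from_csv(cls, manifest_path: str | Path) -> "TruthManifest":
        manifest_path = Path(manifest_path)
        base = manifest_path.parent

        def resolve(p: str) -> str:
            path = Path(p)
            return str(path if path.is_absolute() else base / path)

        df = pd.read_csv(manifest_path)
        scans = [
            ScanRecord(
                scan_id=row.scan_id,
                cultivar=row.cultivar,
                header_path=resolve(row.header_path),
                white_header_path=resolve(row.white_header_path),
                dark_header_path=resolve(row.dark_header_path),
            )
            for row in df.itertuples()
        ]
        return cls(scans=scans)


def _truth_stats(labels: np.ndarray, n_seeds: int):
    centroids, counts = [], []
    for lab in range(1, n_seeds + 1):
        ys, xs = np.nonzero(labels == lab)
        centroids.append((float(ys.mean()), float(xs.mean())))
        counts.append(int(ys.size))
    return centroids, counts


def generate_dataset(
    out_dir: str | Path,
    n_cultivars: int = 10,
    scans_per_cultivar: int = 10,
    scene: SceneConfig | None = None,
    rng_seed: int = 0,
    separation: float = 0.01,
    noise_sd: float = 5.0,
) -> TruthManifest:
    """Write a full synthetic dataset of ENVI scan pairs plus references.

    One white/dark reference pair is written for the whole dataset — the
    illumination field is a property of the acquisition session, not of an
    individual scan.  The manifest (``manifest.csv`` + per-seed
    ``seeds.csv``) is written only after every scan is on disk; a failure
    part-way raises an error listing the scans that were completed.
    Deterministic (byte-identical files) in ``rng_seed``.
    """
    out_dir = Path(out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = SceneConfig() if scene is None else scene
    axis = default_wavelength_axis()
    signatures = make_signatures(n_cultivars, axis, separation=separation, rng_seed=rng_seed)

    # one sub-seed per scan, plus one for the references
    ss = np.random.SeedSequence(rng_seed)
    scan_seeds = [int(s) % (2**31) for s in ss.generate_state(n_cultivars * scans_per_cultivar + 1)]

    ref_scene = replace(scene, rng_seed=scan_seeds[-1])
    _, white, dark, _ = render_scan(signatures[0], ref_scene, noise_sd=noise_sd)
    white_hdr, _ = write_envi(white, out_dir / "white_reference", "white reference (0.99 target)")
    dark_hdr, _ = write_envi(dark, out_dir / "dark_reference", "dark reference")

    records: list[ScanRecord] = []
    completed: list[str] = []
    try:
        k = 0
        for sig in signatures:
            for rep in range(scans_per_cultivar):
                scan_id = f"{sig.cultivar_name}_{rep:02d}"
                scan_scene = replace(scene, rng_seed=scan_seeds[k])
                k += 1
                raw, _, _, truth = render_scan(sig, scan_scene, noise_sd=noise_sd)
                hdr, _ = write_envi(raw, out_dir / scan_id, f"scan {scan_id}")
                centroids, counts = _truth_stats(truth.labels, truth.n_seeds)
                records.append(
                    ScanRecord(
                        scan_id=scan_id,
                        cultivar=sig.cultivar_name,
                        header_path=str(hdr),
                        white_header_path=str(white_hdr),
                        dark_header_path=str(dark_hdr),
                        seed_centroids=centroids,
                        seed_pixel_counts=counts,
                    )
                )
                completed.append(scan_id)
    except Exception as exc:
        raise RuntimeError(
            f"dataset generation failed after {len(completed)} scans "
            f"({', '.join(completed[-3:]) or 'none'} ...): {exc}; manifest not written"
        ) from exc

    manifest = TruthManifest(scans=records)
    manifest.to_csv(out_dir / "manifest.csv", out_dir / "seeds.csv")
    return manifest
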