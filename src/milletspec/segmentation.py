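"""Two-mask seed segmentation and per-seed mean-spectrum extraction.

The first mask thresholds a single band (nearest 1050 nm) of the calibrated
reflectance cube to separate seeds from the dark stage; connected-component
labelling then assigns each seed its own integer so a second, per-seed mask
is just an equality test on the label image.  The mean spectrum over each
seed's pixels is the unit of all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .envi import ReflectanceCube

__all__ = [
    "SeedLabelMap",
    "SpectraTable",
    "background_mask",
    "label_seeds",
    "extract_mean_spectra",
]

ANNOTATION_COLUMNS = ("cultivar", "scan_id", "seed_index", "pixel_count")


@dataclass
class SeedLabelMap:
    """Integer image assigning each pixel to background (0) or a seed (1..n)."""

    labels: np.ndarray
    n_seeds: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer-valued")
        mx = int(self.labels.max(initial=0))
        if self.labels.min(initial=0) < 0 or mx > self.n_seeds:
            raise ValueError(
                f"label values must lie in 0..{self.n_seeds}, found range "
                f"[{int(self.labels.min())}, {mx}]"
            )

    def mask_for(self, seed_index: int) -> np.ndarray:
        """Second mask of the two-mask procedure: pixels of one seed."""
        return self.labels == seed_index


@dataclass
class SpectraTable:
    """Per-seed mean spectra with cultivar/scan/seed annotations.

    ``spectra`` is ``(n_seeds_total, n_bands)``; ``annotations`` is a
    DataFrame with one row per spectrum carrying at least cultivar, scan_id,
    seed_index and pixel_count.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (rows x bands) matrix")
        if self.wavelengths.size != self.spectra.shape[1]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths for {self.spectra.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain missing or non-finite values")
        if len(self.annotations) != self.spectra.shape[0]:
            raise ValueError("annotation rows must match spectra rows")

    @property
    def n_rows(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.annotations["cultivar"].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{w:.2f}" for w in self.wavelengths]
        df = pd.DataFrame(self.spectra, columns=cols)
        return pd.concat([self.annotations.reset_index(drop=True), df], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraTable":
        ann_cols = [c for c in df.columns if c in ANNOTATION_COLUMNS]
        band_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
        return cls(
            spectra=df[band_cols].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in band_cols]),
            annotations=df[ann_cols].copy(),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpectraTable":
        return cls.from_dataframe(pd.read_csv(path))

    @staticmethod
    def concat(tables: list["SpectraTable"]) -> "SpectraTable":
        if not tables:
            raise ValueError("cannot concatenate zero tables")
        wl = tables[0].wavelengths
        for t in tables[1:]:
            if not np.allclose(t.wavelengths, wl):
                raise ValueError("tables have different wavelength axes")
        return SpectraTable(
            spectra=np.vstack([t.spectra for t in tables]),
            wavelengths=wl.copy(),
            annotations=pd.concat([t.annotations for t in tables], ignore_index=True),
        )


def background_mask(
    cube: ReflectanceCube,
    band_nm: float = 1050.0,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """First mask: foreground/background split on the band nearest ``band_nm``.

    ``method='otsu'`` picks the threshold maximising between-class variance
    of that band's histogram; ``method='fixed'`` uses ``fixed_threshold``.
    Returns ``(mask, threshold_used)``; pixels strictly above the threshold
    are foreground.
    """
    wl = cube.wavelengths
    if not (wl[0] <= band_nm <= wl[-1]):
        raise ValueError(
            f"band_nm={band_nm} outside the wavelength span [{wl[0]:.2f}, {wl[-1]:.2f}] nm"
        )
    band = int(np.argmin(np.abs(wl - band_nm)))
    img = cube.cube[:, :, band]
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:  # constant frame: nothing above its own level
            thr = float(img.flat[0])
        else:
            thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown method '{method}' (expected 'otsu' or 'fixed')")
    return img > thr, thr


def label_seeds(mask: np.ndarray, connectivity: int = 8, min_area: int = 10) -> SeedLabelMap:
    """Connected-component labelling of the foreground mask.

    Components smaller than ``min_area`` pixels are dropped (specks);
    surviving components are numbered 1..n in raster-scan order of their
    first pixel.  An empty mask yields ``n_seeds=0``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    mask = mask.astype(bool)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")

    raw_labels, n_raw = ndimage.label(mask, structure=structure)
    if n_raw == 0:
        return SeedLabelMap(labels=raw_labels.astype(np.int32), n_seeds=0, n_dropped=0)

    areas = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
    keep = np.nonzero(areas[1:] >= min_area)[0] + 1  # ascending == raster order of first pixel
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return SeedLabelMap(
        labels=remap[raw_labels],
        n_seeds=int(keep.size),
        n_dropped=int(n_raw - keep.size),
    )


def extract_mean_spectra(
    cube: ReflectanceCube,
    labelmap: SeedLabelMap,
    annotations: dict | None = None,
) -> SpectraTable:
    """Mean reflectance spectrum of every labelled seed.

    Row ``i`` (0-based) is the arithmetic per-band mean over pixels with
    label ``i+1``; rows are ordered by label.  ``annotations`` supplies
    constant per-scan fields (e.g. ``cultivar``, ``scan_id``).
    """
    labels = labelmap.labels
    if labels.shape != cube.cube.shape[:2]:
        raise ValueError(
            f"label image shape {labels.shape} does not match cube spatial dims {cube.cube.shape[:2]}"
        )
    n = labelmap.n_seeds
    flat_labels = labels.ravel()
    flat_cube = cube.cube.reshape(-1, cube.bands)
    counts = np.bincount(flat_labels, minlength=n + 1)
    if np.any(counts[1 : n + 1] == 0):
        empty = int(np.argmin(counts[1 : n + 1])) + 1
        raise ValueError(f"label {empty} has zero pixels; label map is inconsistent")

    sums = np.zeros((n + 1, cube.bands))
    np.add.at(sums, flat_labels, flat_cube)
    means = sums[1:] / counts[1:, None]

    ann = pd.DataFrame(
        {
            "seed_index": np.arange(1, n + 1),
            "pixel_count": counts[1 : n + 1],
        }
    )
    for key, val in (annotations or {}).items():
        ann[key] = val
    order = [c for c in ANNOTATION_COLUMNS if c in ann.columns] + [
        c for c in ann.columns if c not in ANNOTATION_COLUMNS
    ]
    return SpectraTable(spectra=means, wavelengths=cube.wavelengths.copy(), annotations=ann[order])
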