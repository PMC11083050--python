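"""Spectral preprocessing chain for per-seed mean spectra.

Four steps in fixed order:

1. edge trimming — drop the first 6 and last 15 bands, where detector
   response rolls off and spectra are noisy (254 -> 233 bands);
2. maximum normalization — divide each spectrum by its own maximum;
3. Savitzky–Golay smoothing — 27-point window, quadratic local fit;
4. SNV (standard normal variate) — per-spectrum standardization to mean 0,
   sd 1 (sample sd, n-1 denominator), compensating particle-size scattering
   and path-length effects.

Every step is row-independent: a spectrum's output depends only on itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .segmentation import SpectraTable

__all__ = [
    "PreprocessConfig",
    "trim_bands",
    "max_normalize",
    "savgol_smooth",
    "snv",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    trim_start: int = 6
    trim_end: int = 15
    sg_window: int = 27
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.trim_start < 0 or self.trim_end < 0:
            raise ValueError("trims must be non-negative")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and exceed sg_polyorder; got window="
                f"{self.sg_window}, polyorder={self.sg_polyorder}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PreprocessConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown preprocessing keys: {sorted(unknown)}")
        return cls(**{k: int(v) for k, v in mapping.items()})


def trim_bands(table: SpectraTable, cfg: PreprocessConfig | None = None) -> SpectraTable:
    """Drop ``trim_start`` leading and ``trim_end`` trailing bands."""
    cfg = cfg or PreprocessConfig()
    n = table.n_bands
    if n <= cfg.trim_start + cfg.trim_end:
        raise ValueError(
            f"cannot trim {cfg.trim_start}+{cfg.trim_end} bands from a {n}-band table"
        )
    stop = n - cfg.trim_end
    return SpectraTable(
        spectra=table.spectra[:, cfg.trim_start : stop].copy(),
        wavelengths=table.wavelengths[cfg.trim_start : stop].copy(),
        annotations=table.annotations.copy(),
    )


def _rowwise(x: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("expected a spectrum (1-D) or a matrix of row spectra (2-D)")


def max_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale each spectrum by its maximum so the peak equals 1. Idempotent."""
    rows, squeeze = _rowwise(spectrum)
    maxima = rows.max(axis=1)
    if np.any(maxima <= 0):
        bad = int(np.argmax(maxima <= 0))
        raise ValueError(f"row {bad}: maximum is {maxima[bad]:g}, must be positive")
    out = rows / maxima[:, None]
    return out[0] if squeeze else out


def savgol_smooth(spectrum: np.ndarray, window: int = 27, polyorder: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing (derivative order 0).

    Interior points use the standard convolution weights; edge points are
    evaluated from a polynomial fitted to the edge window (no padding).
    Polynomials of degree <= ``polyorder`` pass through unchanged.
    """
    rows, squeeze = _rowwise(spectrum)
    if rows.shape[1] < window:
        raise ValueError(
            f"spectrum length {rows.shape[1]} is shorter than the smoothing window {window}"
        )
    out = savgol_filter(rows, window_length=window, polyorder=polyorder, axis=1, mode="interp")
    return out[0] if squeeze else out


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd with sample sd."""
    rows, squeeze = _rowwise(spectrum)
    if rows.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mean = rows.mean(axis=1)
    sd = rows.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"row {bad}: zero variance, SNV undefined")
    out = (rows - mean[:, None]) / sd[:, None]
    return out[0] if squeeze else out


def preprocess_pipeline(table: SpectraTable, cfg: PreprocessConfig | None = None) -> SpectraTable:
    """Apply trim -> max-normalize -> Savitzky–Golay -> SNV row-wise."""
    cfg = cfg or PreprocessConfig()
    trimmed = trim_bands(table, cfg)
    try:
        x = max_normalize(trimmed.spectra)
        x = savgol_smooth(x, cfg.sg_window, cfg.sg_polyorder)
        x = snv(x)
    except ValueError as exc:
        raise ValueError(f"preprocessing failed: {exc}") from exc
    return SpectraTable(
        spectra=x,
        wavelengths=trimmed.wavelengths,
        annotations=table.annotations.copy(),
    )
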