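"""White/dark reference calibration of raw scans to relative reflectance.

Raw digital numbers are converted band-wise and pixel-wise with

    R = (R0 - Rd) / (Rw - Rd)

where R0 is the raw scan, Rd a dark-current frame (lens capped, lights off)
and Rw a frame of a ~99% reflective white target.  The correction removes
both the illumination field and the detector's dark current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import RawScan, ReflectanceCube

__all__ = ["ReferenceFrames", "calibrate"]


@dataclass
class ReferenceFrames:
    """A white and a dark reference frame sharing the target scan's geometry.

    ``min_white_over_dark``: minimum fraction of pixel-bands on which the
    white frame must exceed the dark frame; a lower observed fraction means
    the references are swapped or corrupt and calibration refuses to run.
    """

    white: RawScan
    dark: RawScan
    min_white_over_dark: float = 0.999

    def __post_init__(self) -> None:
        if self.white.cube.shape != self.dark.cube.shape:
            raise ValueError(
                f"white {self.white.cube.shape} and dark {self.dark.cube.shape} "
                "reference frames must share shape"
            )
        if not np.allclose(self.white.wavelengths, self.dark.wavelengths):
            raise ValueError("white and dark references have different wavelength axes")


def _check_geometry(raw: RawScan, ref: RawScan, name: str) -> None:
    for axis, (a, b) in enumerate(zip(raw.cube.shape, ref.cube.shape)):
        if a != b:
            axis_name = ("lines", "samples", "bands")[axis]
            raise ValueError(
                f"{name} reference disagrees with raw scan on the {axis_name} axis: {b} vs {a}"
            )
    if not np.allclose(raw.wavelengths, ref.wavelengths):
        raise ValueError(f"{name} reference wavelength axis differs from the raw scan's")


def calibrate(raw: RawScan, refs: ReferenceFrames) -> ReflectanceCube:
    """Apply the white/dark correction elementwise.

    Pixel-bands where white == dark have no dynamic range; they are set to 0
    and their count recorded under ``provenance['n_degenerate']``.  Values
    outside [0, 1] (sensor noise) are retained, not clipped, so that
    downstream scatter-correction statistics stay unbiased.
    """
    _check_geometry(raw, refs.white, "white")
    _check_geometry(raw, refs.dark, "dark")

    white = refs.white.cube.astype(float)
    dark = refs.dark.cube.astype(float)
    denom = white - dark

    frac_ok = float(np.mean(denom > 0))
    if frac_ok < refs.min_white_over_dark:
        raise ValueError(
            f"white exceeds dark on only {frac_ok:.4%} of pixel-bands "
            f"(required >= {refs.min_white_over_dark:.4%}); check the reference frames"
        )

    degenerate = denom == 0
    n_degenerate = int(degenerate.sum())
    safe = np.where(degenerate, 1.0, denom)
    refl = (raw.cube.astype(float) - dark) / safe
    refl[degenerate] = 0.0

    return ReflectanceCube(
        cube=refl,
        wavelengths=raw.wavelengths.copy(),
        provenance={
            "raw": raw.metadata.get("description", "raw"),
            "white": refs.white.metadata.get("description", "white"),
            "dark": refs.dark.metadata.get("description", "dark"),
            "n_degenerate": n_degenerate,
        },
    )
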