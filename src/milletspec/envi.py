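"""Reading and writing ENVI-style hypercube file pairs.

A scan lives on disk as a binary cube (``*.raw`` for digital numbers,
``*.dat`` for reflectance) next to a plain-text ``*.hdr`` header that
declares the spatial dimensions, band count, data type, interleave and the
wavelength axis in nanometres.  In memory every cube is a single
``(lines, samples, bands)`` array regardless of the on-disk interleave.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RawScan", "ReflectanceCube", "read_envi", "write_envi"]

# ENVI data-type codes -> numpy dtypes (little-endian assumed; byte order 0)
_DTYPE_BY_CODE = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_CODE_BY_KIND = {"u2": 12, "u1": 1, "i2": 2, "i4": 3, "f4": 4, "f8": 5}


def _check_axis(wavelengths: np.ndarray, n_bands: int) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size != n_bands:
        raise ValueError(
            f"wavelength axis has {wl.size} entries but the cube has {n_bands} bands"
        )
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise ValueError(
            f"wavelength axis must be strictly increasing; "
            f"axis[{bad + 1}]={wl[bad + 1]:g} does not exceed axis[{bad}]={wl[bad]:g}"
        )
    return wl


@dataclass
class RawScan:
    """Uncalibrated digital-number hypercube with header metadata.

    ``cube`` is ``(lines, samples, bands)``; ``wavelengths`` gives the band
    centres in nm and must be strictly increasing.
    """

    cube: np.ndarray
    wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be 3-D (lines, samples, bands), got ndim={self.cube.ndim}")
        if min(self.cube.shape) < 1:
            raise ValueError(f"all cube dimensions must be >= 1, got shape {self.cube.shape}")
        self.wavelengths = _check_axis(self.wavelengths, self.cube.shape[2])

    @property
    def lines(self) -> int:
        return self.cube.shape[0]

    @property
    def samples(self) -> int:
        return self.cube.shape[1]

    @property
    def bands(self) -> int:
        return self.cube.shape[2]


@dataclass
class ReflectanceCube:
    """Calibrated relative-reflectance cube.

    Shares the shape contract of :class:`RawScan`.  ``provenance`` records the
    identities of the raw/white/dark sources and the count of degenerate
    (white == dark) pixel-bands zeroed during calibration.  Values slightly
    outside [0, 1] are legitimate noise and are retained.
    """

    cube: np.ndarray
    wavelengths: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be 3-D (lines, samples, bands), got ndim={self.cube.ndim}")
        if min(self.cube.shape) < 1:
            raise ValueError(f"all cube dimensions must be >= 1, got shape {self.cube.shape}")
        if not np.all(np.isfinite(self.cube)):
            raise ValueError("reflectance cube contains non-finite values")
        self.wavelengths = _check_axis(self.wavelengths, self.cube.shape[2])

    @property
    def lines(self) -> int:
        return self.cube.shape[0]

    @property
    def samples(self) -> int:
        return self.cube.shape[1]

    @property
    def bands(self) -> int:
        return self.cube.shape[2]


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a key -> string/list map (lowercase keys)."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header: missing leading 'ENVI' magic line")
    body = text.lstrip()[4:]
    fields: dict = {}
    # key = { multi, line, block } | key = scalar
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            inner = val[1:-1]
            fields[key] = [v.strip() for v in inner.replace("\n", " ").split(",") if v.strip()]
        else:
            fields[key] = val
        pos = m.end()
    return fields


def read_envi(header_path: str | Path) -> RawScan:
    """Read an ENVI header/cube pair into a :class:`RawScan`.

    The cube file is located from the header's ``data file`` entry if present,
    otherwise by swapping the header suffix for ``.raw``/``.dat``/``.img``.
    BIL, BIP and BSQ interleaves are accepted; the returned cube is always
    ``(lines, samples, bands)``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    fields = _parse_header(header_path.read_text())

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"header {header_path} is missing required field '{required}'")
    if "wavelength" not in fields:
        raise ValueError(f"header {header_path} is missing required field 'wavelength'")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPE_BY_CODE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_DTYPE_BY_CODE[code])
    interleave = str(fields["interleave"]).lower()
    wavelengths = np.array([float(v) for v in fields["wavelength"]])
    offset = int(fields.get("header offset", 0))

    if "data file" in fields:
        cube_path = header_path.parent / str(fields["data file"])
    else:
        for suffix in (".raw", ".dat", ".img", ".bin"):
            cube_path = header_path.with_suffix(suffix)
            if cube_path.exists():
                break
        else:
            raise FileNotFoundError(f"no cube file found next to {header_path}")
    if not cube_path.exists():
        raise FileNotFoundError(f"cube file not found: {cube_path}")

    expected = lines * samples * bands * dtype.itemsize + offset
    actual = cube_path.stat().st_size
    if expected != actual:
        raise ValueError(
            f"cube size mismatch for {cube_path}: header declares "
            f"{lines}x{samples}x{bands} {dtype.name} = {expected} bytes, file has {actual} bytes"
        )

    flat = np.fromfile(cube_path, dtype=dtype, offset=offset)
    if interleave == "bil":  # (lines, bands, samples)
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        cube = flat.reshape(lines, samples, bands)
    elif interleave == "bsq":  # (bands, lines, samples)
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave '{interleave}' (expected bil, bip or bsq)")

    metadata = dict(fields)
    metadata.pop("wavelength", None)
    return RawScan(cube=np.ascontiguousarray(cube), wavelengths=wavelengths, metadata=metadata)


def _dtype_code(arr: np.ndarray) -> tuple[int, np.dtype]:
    """On-disk type policy: integer data -> uint16, float data -> float32."""
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise ValueError("integer cube values outside the uint16 on-disk range")
        return 12, np.dtype(np.uint16)
    return 4, np.dtype(np.float32)


def write_envi(
    scan: RawScan | ReflectanceCube,
    out_stem: str | Path,
    description: str = "milletspec scan",
) -> tuple[Path, Path]:
    """Write a scan as a ``.hdr``/``.raw`` pair in BIL interleave.

    Integer cubes are stored as unsigned 16-bit, float cubes as 32-bit float.
    Returns ``(header_path, cube_path)``.
    """
    out_stem = Path(out_stem)
    out_stem.parent.mkdir(parents=True, exist_ok=True)
    code, dtype = _dtype_code(scan.cube)
    header_path = out_stem.with_suffix(".hdr")
    cube_path = out_stem.with_suffix(".raw")

    bil = np.ascontiguousarray(scan.cube.transpose(0, 2, 1)).astype(dtype)
    try:
        bil.tofile(cube_path)
    except OSError as exc:
        raise OSError(f"cannot write cube file {cube_path}: {exc}") from exc

    wl = ", ".join(f"{w:.6f}" for w in scan.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{ {description} }}\n"
        f"samples = {scan.samples}\n"
        f"lines = {scan.lines}\n"
        f"bands = {scan.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"data file = {cube_path.name}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return header_path, cube_path
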