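"""Hyperspectral cube I/O, reflectance calibration, and VNIR/SWIR fusion.

The acquisition side of the pipeline produces raw-count image cubes plus
white-reference (a ~99% reflectance ceramic panel) and black-reference
(shutter closed / dark current) frames.  :func:`calibrate_reflectance`
normalises raw counts to reflectance band by band,

    R = (R_o - R_b) / (R_w - R_b),

after which per-sample mean spectra are extracted over a region-of-interest
mask and the two sensor grids are fused onto a single working grid.

ENVI (header text file + flat binary) is the de-facto container for such
cubes; a minimal reader/writer supporting BIL/BIP/BSQ interleaves and both
byte orders is provided here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import SWIR, VNIR, WavelengthGrid

CUBE_KINDS = ("raw", "white", "black", "reflectance")

# soft plausibility envelope for calibrated reflectance (real panels let
# bright samples exceed 1 slightly)
_REFL_SOFT_LO, _REFL_SOFT_HI = -0.1, 1.5


@dataclass
class HyperCube:
    """A rows x cols x bands intensity block tied to a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"band dimension {self.values.shape[2]} != grid length {len(self.grid)}"
            )
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"kind must be one of {CUBE_KINDS}, got {self.kind!r}")
        if self.kind == "reflectance":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < _REFL_SOFT_LO or hi > _REFL_SOFT_HI:
                warnings.warn(
                    f"reflectance values outside [{_REFL_SOFT_LO}, {_REFL_SOFT_HI}] "
                    f"(range [{lo:.3g}, {hi:.3g}]); check the calibration frames",
                    stacklevel=2,
                )

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]


@dataclass
class ROIMask:
    """Boolean pixel mask delineating the sample within the image plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# ENVI container

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse the `key = value` / `key = { ... }` lines of an ENVI header."""
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_block:
            buf.append(line.rstrip("}").strip())
            if line.endswith("}"):
                fields[key] = " ".join(buf)
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{"):
            inner = val[1:].strip()
            if inner.endswith("}"):
                fields[key] = inner.rstrip("}").strip()
            else:
                buf = [inner] if inner else []
                in_block = True
        else:
            fields[key] = val
    return fields


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    The binary path is the header path with its extension dropped, or with
    ``.img`` appended, whichever exists.  The wavelength list in the header
    becomes the cube's grid; a header without one is rejected by name.
    """
    header_path = Path(header_path)
    text = header_path.read_text()
    fields = _parse_envi_header(text)

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"ENVI header missing required field '{required}'")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required field 'wavelength'")

    samples = int(fields["samples"])   # columns
    lines = int(fields["lines"])       # rows
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header field 'wavelength' lists {wavelengths.size} values "
            f"but 'bands' = {bands}"
        )

    binary = header_path.with_suffix("")
    if not binary.exists():
        binary = header_path.with_suffix(".img")
    if not binary.exists():
        raise FileNotFoundError(f"no binary found for header {header_path}")
    flat = np.fromfile(binary, dtype=dtype)
    if flat.size != samples * lines * bands:
        raise ValueError("binary size does not match header dimensions")

    if interleave == "bsq":          # (bands, lines, samples)
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":        # (lines, bands, samples)
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                            # bip: (lines, samples, bands)
        cube = flat.reshape(lines, samples, bands)

    kind = fields.get("hsiq kind", "raw")
    if kind not in CUBE_KINDS:
        kind = "raw"
    return HyperCube(values=cube.astype(float), grid=WavelengthGrid(wavelengths), kind=kind)


def write_envi_cube(
    cube: HyperCube,
    header_path: str | Path,
    interleave: str = "bil",
    dtype: str = "float64",
    byte_order: int = 0,
) -> Path:
    """Write a cube as an ENVI header + flat binary; returns the binary path."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    np_dtype = np.dtype(dtype).newbyteorder(">" if byte_order == 1 else "<")
    rows, cols, bands = cube.values.shape

    if interleave == "bsq":
        arr = cube.values.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.values.transpose(0, 2, 1)
    else:
        arr = cube.values
    binary_path = header_path.with_suffix(".img")
    arr.astype(np_dtype).tofile(binary_path)

    wl = ", ".join(f"{c:.4f}" for c in cube.grid.centers)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        f"byte order = {byte_order}\n"
        f"hsiq kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return binary_path


# ---------------------------------------------------------------------------
# Calibration and extraction


def calibrate_reflectance(
    raw: HyperCube, white: HyperCube, black: HyperCube
) -> HyperCube:
    """Black/white-plate correction: R = (R_o - R_b) / (R_w - R_b).

    All three cubes must share one grid and spatial shape.  Bands where the
    white and black references coincide anywhere are reported by index and
    rejected rather than silently producing NaN.
    """
    if not (raw.grid == white.grid == black.grid):
        raise ValueError("raw/white/black cubes must share one wavelength grid")
    if not (raw.values.shape == white.values.shape == black.values.shape):
        raise ValueError("raw/white/black cubes must share spatial shape")
    expected = {"raw": raw, "white": white, "black": black}
    for kind, cube in expected.items():
        if cube.kind != kind:
            raise ValueError(f"expected a {kind!r} cube, got kind {cube.kind!r}")

    denom = white.values - black.values
    bad = np.flatnonzero(np.any(denom == 0.0, axis=(0, 1)))
    if bad.size:
        raise ValueError(
            f"white and black references coincide in bands {bad.tolist()}; "
            "cannot calibrate"
        )
    refl = (raw.values - black.values) / denom
    return HyperCube(values=refl, grid=raw.grid, kind="reflectance")


def extract_roi_mean(cube: HyperCube, roi: ROIMask) -> np.ndarray:
    """Mean spectrum over the masked pixels of a reflectance cube."""
    if cube.kind != "reflectance":
        raise ValueError("ROI extraction expects a calibrated reflectance cube")
    if roi.mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if roi.n_pixels == 0:
        raise ValueError("ROI mask selects no pixels")
    return cube.values[roi.mask].mean(axis=0)


def merge_sensor_bands(
    vnir_spectrum: np.ndarray,
    vnir_grid: WavelengthGrid,
    swir_spectrum: np.ndarray,
    swir_grid: WavelengthGrid,
    boundary_nm: float = 990.0,
    seam_from_swir: bool = True,
) -> tuple[np.ndarray, WavelengthGrid]:
    """Fuse VNIR and SWIR mean spectra onto one working grid.

    VNIR bands strictly below the seam are kept, SWIR bands at/above it are
    appended; where the sensors overlap the SWIR camera is native at the
    seam, so a band at exactly the boundary is taken from SWIR by default
    (``seam_from_swir=False`` flips the convention).  No resampling is done:
    the fused grid is the union of the retained native bands.
    """
    vnir_spectrum = np.asarray(vnir_spectrum, dtype=float)
    swir_spectrum = np.asarray(swir_spectrum, dtype=float)
    if vnir_spectrum.size != len(vnir_grid) or swir_spectrum.size != len(swir_grid):
        raise ValueError("spectrum length must match its grid")

    if seam_from_swir:
        keep_v = vnir_grid.centers < boundary_nm
        keep_s = swir_grid.centers >= boundary_nm
    else:
        keep_v = vnir_grid.centers <= boundary_nm
        keep_s = swir_grid.centers > boundary_nm

    centers = np.concatenate([vnir_grid.centers[keep_v], swir_grid.centers[keep_s]])
    spectrum = np.concatenate([vnir_spectrum[keep_v], swir_spectrum[keep_s]])
    if centers.size == 0 or np.any(np.diff(centers) <= 0):
        raise ValueError("fused grid is empty or non-monotone; check sensor ranges")
    tags = tuple([VNIR] * int(keep_v.sum()) + [SWIR] * int(keep_s.sum()))
    return spectrum, WavelengthGrid(centers=centers, sensor_tags=tags)
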