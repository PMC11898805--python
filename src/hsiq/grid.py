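"""Wavelength grids for fused VNIR/SWIR spectra.

A dual-sensor hyperspectral rig covers the visible/near-infrared
(~400-1000 nm) and short-wave infrared (~1000-2500 nm) ranges with two
separate cameras.  Downstream chemometrics operates on a single fused
band axis; :class:`WavelengthGrid` carries the band centers together with
a per-band tag recording which sensor the band came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VNIR = "VNIR"
SWIR = "SWIR"

#: Working-grid defaults: 396 bands spanning 410-2500 nm, sensors seamed at 990 nm.
DEFAULT_N_BANDS = 396
DEFAULT_RANGE_NM = (410.0, 2500.0)
DEFAULT_BOUNDARY_NM = 990.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers (nm) with sensor provenance tags.

    Parameters
    ----------
    centers
        Strictly increasing band centers in nanometres, all within
        [410, 2500] for the default instrument envelope.
    sensor_tags
        One of ``"VNIR"`` / ``"SWIR"`` per band.
    """

    centers: np.ndarray
    sensor_tags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("grid needs a 1-D, non-empty center array")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if not self.sensor_tags:
            tags = tuple(
                VNIR if c < DEFAULT_BOUNDARY_NM else SWIR for c in centers
            )
            object.__setattr__(self, "sensor_tags", tags)
        elif len(self.sensor_tags) != centers.size:
            raise ValueError("sensor_tags length must match centers")

    def __len__(self) -> int:
        return int(self.centers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            np.array_equal(self.centers, other.centers)
            and self.sensor_tags == other.sensor_tags
        )

    def indices_in_band(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands whose centers fall in [lo_nm, hi_nm]."""
        return np.flatnonzero((self.centers >= lo_nm) & (self.centers <= hi_nm))


def make_wavelength_grid(
    n_bands: int = DEFAULT_N_BANDS,
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
    vnir_swir_boundary: float = DEFAULT_BOUNDARY_NM,
) -> WavelengthGrid:
    """Build a uniformly spaced fused grid.

    Bands strictly below ``vnir_swir_boundary`` are tagged VNIR, bands at or
    above it SWIR (at the seam the SWIR sensor is native).

    Raises
    ------
    ValueError
        For fewer than 2 bands, an inverted range, or a range outside the
        plausible instrument envelope [350, 2550] nm.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    lo, hi = float(range_nm[0]), float(range_nm[1])
    if lo >= hi:
        raise ValueError(f"inverted wavelength range [{lo}, {hi}]")
    if lo < 350.0 or hi > 2550.0:
        raise ValueError(f"range [{lo}, {hi}] outside instrument envelope [350, 2550]")
    centers = np.linspace(lo, hi, n_bands)
    tags = tuple(VNIR if c < vnir_swir_boundary else SWIR for c in centers)
    return WavelengthGrid(centers=centers, sensor_tags=tags)
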