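"""Seeded generator of synthetic lily reflectance datasets.

No public dataset of sulfur-fumigated lily spectra exists, so the pipeline
is exercised on synthetic two-class data built to carry the statistical
structure the analysis assumes:

* a smooth reflectance baseline (three broad Gaussian humps) common to all
  samples;
* one dedicated Gaussian absorption dip per analyte whose depth is linear
  in that analyte's content — polysaccharide and total phenol sit in the
  SWIR, the SO2 feature is co-located with the fumigation signature;
* a fumigation signature: a raised-cosine reflectance depression over
  1200-1400 nm whose amplitude scales with the sample's SO2 residue, so
  fumigated samples are depressed there and sun-dried samples are not;
* i.i.d. additive Gaussian noise per band, clipped to [0, 1.05] (calibrated
  reflectance may slightly exceed 1 against a ~99% white panel).

Contents are drawn uniformly over configured ranges so that range checks
are exact.  Randomness is counter-split per sample: sample i of a dataset
uses the stream seeded by (seed, i), so growing ``n_samples`` never
reshuffles earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import WavelengthGrid, make_wavelength_grid
from .spectra_io import HyperCube, ROIMask

SUN_DRIED = "sun_dried"
FUMIGATED = "fumigated"
LABELS = (SUN_DRIED, FUMIGATED)

ANALYTES = ("polysaccharide", "phenol", "so2")  # mg/g, mg/g, ug/g

# --- spectral model constants (amplitude, center nm, width nm) -------------
BASELINE_HUMPS = ((0.45, 700.0, 350.0), (0.18, 1500.0, 320.0), (0.15, 2200.0, 260.0))
BASELINE_OFFSET = 0.18
# dedicated analyte absorption features: center nm, width nm, depth per unit content
POLY_FEATURE = (1580.0, 55.0, 4.8e-4)    # depth per mg/g
PHENOL_FEATURE = (2120.0, 50.0, 1.7e-3)  # depth per mg/g
SO2_DEPTH_PER_UG = 1.0e-4                # depth per ug/g at the signature peak

REFLECTANCE_CEILING = 1.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated study: 500 sample batches, half
    sulfur-fumigated, with the fumigation signature planted between
    1200 and 1400 nm.
    """

    n_samples: int = 500
    fumigated_fraction: float = 0.5
    signature_band: tuple[float, float] = (1200.0, 1400.0)
    signature_depth: float = 0.1
    content_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "polysaccharide": (50.0, 250.0),
            "phenol": (5.0, 60.0),
            "so2": (100.0, 400.0),
        }
    )
    so2_sundried_floor: float = 5.0
    noise_sd: float = 0.02
    seed: int = 0
    n_bands: int = 396
    range_nm: tuple[float, float] = (410.0, 2500.0)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.fumigated_fraction <= 1.0:
            raise ValueError("fumigated_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.signature_band
        if not (410.0 <= lo < hi <= 2500.0):
            raise ValueError("signature_band must be a proper interval in [410, 2500]")
        for analyte in ANALYTES:
            if analyte not in self.content_ranges:
                raise ValueError(f"content_ranges missing analyte {analyte!r}")
            a, b = self.content_ranges[analyte]
            if not (0 <= a < b):
                raise ValueError(f"degenerate content range for {analyte!r}: ({a}, {b})")

    def grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.n_bands, self.range_nm)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["signature_band"] = list(d["signature_band"])
        d["range_nm"] = list(d["range_nm"])
        d["content_ranges"] = {k: list(v) for k, v in d["content_ranges"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("signature_band", "range_nm"):
            if key in d:
                d[key] = tuple(d[key])
        if "content_ranges" in d:
            d["content_ranges"] = {k: tuple(v) for k, v in d["content_ranges"].items()}
        return cls(**d)


@dataclass
class SampleRecord:
    """One sample: mean reflectance spectrum, class label, reference contents."""

    spectrum: np.ndarray
    label: str
    contents: dict[str, float]
    sample_id: str

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if any(v < 0 for v in self.contents.values()):
            raise ValueError("contents must be non-negative")


@dataclass
class Dataset:
    """An ordered collection of records sharing one wavelength grid."""

    records: list[SampleRecord]
    grid: WavelengthGrid
    provenance: SyntheticConfig | dict | None = None

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for r in self.records:
            if r.spectrum.size != len(self.grid):
                raise ValueError("record spectrum length != grid length")

    def __len__(self) -> int:
        return len(self.records)

    # ----- convenient matrix views -----
    def spectra(self) -> np.ndarray:
        return np.stack([r.spectrum for r in self.records])

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def contents(self, analyte: str) -> np.ndarray:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return np.array([r.contents[analyte] for r in self.records])

    def subset(self, indices: np.ndarray) -> "Dataset":
        return Dataset(
            records=[self.records[i] for i in indices],
            grid=self.grid,
            provenance=self.provenance,
        )

    def to_csv(self, path: str | Path) -> None:
        """One row per sample: id, label, the three contents, then one
        reflectance column per wavelength (header = center in nm)."""
        cols = {"sample_id": [r.sample_id for r in self.records],
                "label": [r.label for r in self.records]}
        for analyte in ANALYTES:
            cols[analyte] = [r.contents[analyte] for r in self.records]
        spectra = self.spectra()
        for j, c in enumerate(self.grid.centers):
            cols[f"{c:.4f}"] = spectra[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        df = pd.read_csv(path)
        meta = ["sample_id", "label", *ANALYTES]
        wl_cols = [c for c in df.columns if c not in meta]
        grid = WavelengthGrid(np.array([float(c) for c in wl_cols]))
        records = [
            SampleRecord(
                spectrum=row[wl_cols].to_numpy(dtype=float),
                label=row["label"],
                contents={a: float(row[a]) for a in ANALYTES},
                sample_id=str(row["sample_id"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, grid=grid, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Spectral forward model


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def baseline_reflectance(grid: WavelengthGrid) -> np.ndarray:
    """Smooth sample-independent baseline: offset plus three broad humps."""
    wl = grid.centers
    base = np.full_like(wl, BASELINE_OFFSET)
    for amp, center, width in BASELINE_HUMPS:
        base += amp * _gaussian(wl, center, width)
    return base


def signature_window(grid: WavelengthGrid, band: tuple[float, float]) -> np.ndarray:
    """Raised-cosine window: 1 at the band center, 0 at and outside its edges."""
    lo, hi = band
    wl = grid.centers
    w = np.zeros_like(wl)
    inside = (wl > lo) & (wl < hi)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (wl[inside] - lo) / (hi - lo)))
    return w


def clean_spectrum(
    config: SyntheticConfig,
    label: str,
    contents: dict[str, float],
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Noise-free forward model mapping (label, contents) -> reflectance."""
    grid = grid or config.grid()
    wl = grid.centers
    spec = baseline_reflectance(grid)

    c_p, w_p, k_p = POLY_FEATURE
    spec -= k_p * contents["polysaccharide"] * _gaussian(wl, c_p, w_p)
    c_f, w_f, k_f = PHENOL_FEATURE
    spec -= k_f * contents["phenol"] * _gaussian(wl, c_f, w_f)

    # SO2 feature and fumigation signature share the 1200-1400 nm window:
    # the analyte term is linear in the residue for every sample, the
    # signature term adds a label-dependent depression scaled by the same
    # residue relative to the top of its configured range.
    so2 = contents["so2"]
    so2_max = config.content_ranges["so2"][1]
    depth = SO2_DEPTH_PER_UG * so2
    if label == FUMIGATED:
        depth += config.signature_depth * so2 / so2_max
    spec -= depth * signature_window(grid, config.signature_band)
    return spec


def draw_contents(
    config: SyntheticConfig, label: str, rng: np.random.Generator
) -> dict[str, float]:
    """Uniform content draws; sun-dried SO2 sits at the configured floor."""
    contents = {}
    for analyte in ("polysaccharide", "phenol"):
        lo, hi = config.content_ranges[analyte]
        contents[analyte] = float(rng.uniform(lo, hi))
    if label == FUMIGATED:
        lo, hi = config.content_ranges["so2"]
        contents["so2"] = float(rng.uniform(lo, hi))
    else:
        contents["so2"] = float(config.so2_sundried_floor)
    return contents


def simulate_sample(
    config: SyntheticConfig,
    label: str,
    rng: np.random.Generator,
    sample_id: str = "s0",
    contents: dict[str, float] | None = None,
) -> SampleRecord:
    """Generate one sample record.

    ``contents`` may be supplied explicitly (e.g. to build matched
    fumigated/sun-dried pairs); otherwise they are drawn from the config's
    ranges using ``rng``.  Noise is additive i.i.d. Gaussian per band; the
    result is clipped to [0, 1.05].
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    grid = config.grid()
    if contents is None:
        contents = draw_contents(config, label, rng)
    spec = clean_spectrum(config, label, contents, grid)
    if config.noise_sd > 0:
        spec = spec + rng.normal(0.0, config.noise_sd, size=spec.shape)
    spec = np.clip(spec, 0.0, REFLECTANCE_CEILING)
    return SampleRecord(spectrum=spec, label=label, contents=contents,
                        sample_id=sample_id)


def simulate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate a full dataset under the configured study design.

    The first ``round(n * fumigated_fraction)`` samples are fumigated and
    the remainder sun-dried.  Sample i draws from the stream seeded by
    (seed, i), making the dataset byte-reproducible and extensible.
    """
    n_fum = int(round(config.n_samples * config.fumigated_fraction))
    labels = [FUMIGATED] * n_fum + [SUN_DRIED] * (config.n_samples - n_fum)
    records = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng([config.seed, i])
        records.append(
            simulate_sample(config, label, rng, sample_id=f"s{i:04d}")
        )
    return Dataset(records=records, grid=config.grid(), provenance=config)


# ---------------------------------------------------------------------------
# Raw-frame fixture generation (inverse of the calibration step)

_FRAME_SHAPE = (6, 6)     # full frame; the sample patch is its interior
_PATCH = (slice(1, 5), slice(1, 5))


def simulate_raw_frames(
    record: SampleRecord,
    gain: float = 1000.0,
    offset: float = 100.0,
) -> tuple[HyperCube, HyperCube, HyperCube, ROIMask]:
    """Synthesize raw/white/black frames whose calibration recovers ``record``.

    Per band: black = offset, white = offset + gain, raw = offset + gain * R
    over a 4x4 sample patch centred in a 6x6 frame (background pixels stay at
    the black level).  The returned mask marks the patch, so
    ``extract_roi_mean(calibrate_reflectance(raw, white, black), mask)``
    reproduces the record's spectrum exactly.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    n_bands = record.spectrum.size
    rows, cols = _FRAME_SHAPE
    black = np.full((rows, cols, n_bands), float(offset))
    white = black + gain
    raw = black.copy()
    raw[_PATCH[0], _PATCH[1], :] = offset + gain * record.spectrum

    mask = np.zeros(_FRAME_SHAPE, dtype=bool)
    mask[_PATCH] = True

    grid = make_wavelength_grid(n_bands)
    return (
        HyperCube(raw, grid, kind="raw"),
        HyperCube(white, grid, kind="white"),
        HyperCube(black, grid, kind="black"),
        ROIMask(mask),
    )
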