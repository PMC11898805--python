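"""Reference-chemistry arithmetic for the three ground-truth contents.

Wet-lab reference values behind the spectral models come from colorimetric
kits (polysaccharide at 490 nm, total phenol at 760 nm) read against a
linear standard curve, and from acid-base titration of distilled SO2.
Only the arithmetic is implemented here:

    M1 = 5 * Y / W                      total polysaccharide (mg/g)
    M2 = 2.5 * X / W                    total phenol (mg/g)
    M3 = (A - B) * c * 0.032 * 1e6 / W  SO2 residue (ug/g)

with Y, X the kit concentrations (mg/mL) read off the standard curve,
W the sample mass (g), A/B sample and blank NaOH titrant volumes (mL),
c the titrant molarity (mol/L), and 0.032 g the SO2 equivalent of 1 mL of
1 mol/L NaOH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Kit standard concentrations (mg/mL) for the polysaccharide assay.
POLYSACCHARIDE_STANDARDS = (1.0, 0.5, 0.25, 0.125, 0.0625)
#: Kit standard concentrations (mg/mL) for the total-phenol assay.
PHENOL_STANDARDS = (0.16, 0.08, 0.04, 0.02, 0.01, 0.005)

SO2_EQUIVALENT_G = 0.032  # g SO2 per mL of 1 mol/L NaOH


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance -> concentration calibration."""

    slope: float
    intercept: float
    fit_r2: float

    def concentration(self, absorbance: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


@dataclass(frozen=True)
class TitrationReading:
    """One SO2 titration: sample volume A, blank B (mL), molarity c, mass W."""

    A: float
    B: float
    c: float
    W: float

    def __post_init__(self) -> None:
        if not (self.A >= self.B >= 0):
            raise ValueError("need A >= B >= 0 (blank-corrected titration)")
        if self.c <= 0:
            raise ValueError("titrant molarity c must be positive")
        if self.W <= 0:
            raise ValueError("sample mass W must be positive")


def fit_standard_curve(
    concentrations: np.ndarray, absorbances: np.ndarray
) -> StandardCurve:
    """Least-squares line mapping absorbance to concentration.

    The inverse (absorbance -> concentration) direction is fitted directly,
    matching how the kit concentration enters the content formulas and
    avoiding a divide-by-slope at read time.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape or conc.ndim != 1:
        raise ValueError("concentrations and absorbances must be equal-length 1-D")
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least two distinct standard concentrations")
    if np.unique(absb).size < 2:
        raise ValueError("absorbances are all equal; curve is degenerate")
    res = stats.linregress(absb, conc)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_r2=float(res.rvalue**2),
    )


def polysaccharide_content(Y: float, W: float) -> float:
    """Total polysaccharide M1 = 5*Y/W in mg/g (Y in mg/mL, W in g)."""
    if W <= 0:
        raise ValueError("sample mass W must be positive")
    if Y < 0:
        raise ValueError("concentration Y must be non-negative")
    return 5.0 * Y / W


def total_phenol_content(X: float, W: float) -> float:
    """Total phenol M2 = 2.5*X/W in mg/g (X in mg/mL, W in g)."""
    if W <= 0:
        raise ValueError("sample mass W must be positive")
    if X < 0:
        raise ValueError("concentration X must be non-negative")
    return 2.5 * X / W


def so2_residue(reading: TitrationReading) -> float:
    """SO2 residue M3 = (A-B)*c*0.032*1e6/W in ug/g."""
    return (reading.A - reading.B) * reading.c * SO2_EQUIVALENT_G * 1e6 / reading.W
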