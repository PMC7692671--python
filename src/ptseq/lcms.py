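"""Standard-curve calibration and PT-density arithmetic for LC-MS/MS.

Two calibration designs are supported, matching the bench workflow:

* mononucleosides (dC and dT): HPLC peak area vs concentration in ng/uL,
  over a 0-40 ng/uL ladder;
* Rp PT-dinucleotides (GpsA, GpsT): LC-MS/MS peak-area *ratio* to a fixed
  Sp-configuration internal standard vs concentration in fmol/uL, over a
  0-200 fmol/uL ladder.

From the mole quantities of released mononucleosides and PT dinucleotides
in the hydrolysate, the genomic PT density follows from base pairing
(#A = #T and #C = #G, so total nt = 2*(C + T)):

    density_X = 1e6 * mol_X / (2 * (mol_C + mol_T))   [PT per 1e6 nt]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: molecular weights (g/mol) of the 2'-deoxyribonucleosides, used to turn
#: ng/uL mononucleoside concentrations into mole quantities.  Override by
#: passing an explicit table if a different convention is needed.
NUCLEOSIDE_MW = {"dA": 251.24, "dC": 227.22, "dG": 267.24, "dT": 242.23}


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # ng/uL (mononucleoside) or fmol/uL (dinucleotide)
    response: float       # peak area, or area ratio to the internal standard

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class LinearCurve:
    slope: float
    intercept: float
    r_squared: float
    response_domain: tuple[float, float]  # trusted inversion range


def fit_calibration(points: Sequence[CalibrationPoint]) -> LinearCurve:
    """Ordinary least squares: response = slope*concentration + intercept."""
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration needs at least 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LinearCurve(float(slope), float(intercept), r2,
                       (float(y.min()), float(y.max())))


def invert_calibration(curve: LinearCurve, response: float) -> float:
    """Concentration for a measured response: (response - intercept)/slope."""
    if abs(curve.slope) < 1e-12:
        raise ValueError("cannot invert a flat calibration curve (slope 0)")
    lo, hi = curve.response_domain
    if not lo <= response <= hi:
        warnings.warn(
            f"response {response} outside the calibrated domain "
            f"[{lo}, {hi}]; extrapolating", stacklevel=2)
    return (response - curve.intercept) / curve.slope


def ng_per_ul_to_pmol_per_ul(concentration: float, nucleoside: str,
                             mw_table: dict[str, float] | None = None) -> float:
    """ng/uL -> pmol/uL via the nucleoside molecular weight."""
    mw = (mw_table or NUCLEOSIDE_MW)[nucleoside]
    return concentration / mw * 1000.0


@dataclass(frozen=True)
class HydrolysateQuant:
    """Mole quantities recovered from a nuclease-P1 hydrolysate.

    Any consistent mole unit works; densities are scale-invariant.
    """

    mol_c: float
    mol_t: float
    mol_gpsa: float
    mol_gpst: float

    def __post_init__(self) -> None:
        for name in ("mol_c", "mol_t", "mol_gpsa", "mol_gpst"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_nt(self) -> float:
        # A=T and C=G in duplex DNA, so total nucleotides = 2*(C + T)
        return 2.0 * (self.mol_c + self.mol_t)


def pt_density(quant: HydrolysateQuant) -> dict[str, float]:
    """PT dinucleotides per 1e6 nt for the GpsA and GpsT contexts."""
    total = quant.total_nt
    if total <= 0:
        raise ValueError("total nucleotide quantity must be positive")
    return {
        "GpsA": 1e6 * quant.mol_gpsa / total,
        "GpsT": 1e6 * quant.mol_gpst / total,
    }


def read_calibration_table(path, delimiter: str | None = None,
                           ) -> list[CalibrationPoint]:
    """Two-column delimited text (concentration, response); '#' comments and
    an optional non-numeric header line are skipped."""
    points = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two columns, got {line!r}")
            try:
                conc, resp = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header line
            points.append(CalibrationPoint(conc, resp))
    if not points:
        raise ValueError(f"{path}: no calibration points found")
    return points
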