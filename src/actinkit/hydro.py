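"""Hydrodynamic sizing from gel filtration and density-gradient sedimentation.

Combining a Stokes radius a (Å, from size-exclusion chromatography against
markers of known radius) with a sedimentation coefficient s (S, from a
glycerol gradient against markers of known Svedberg coefficient) gives a
native molecular weight via the Siegel–Monty relation MW = α·a·s, where α
collects solvent viscosity, density, partial specific volume and Avogadro's
number.  Rather than computing α from buffer properties, it is calibrated
empirically as the origin-constrained slope of marker MW against marker a·s.

Shape information comes from the frictional ratio f/f0 relative to the
anhydrous sphere of equal mass, inverted through the Perrin translational
shape function for a prolate ellipsoid of revolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "CalibrationSeries",
    "LinearCalibration",
    "linear_calibration",
    "alpha_from_standards",
    "mw_siegel_monty",
    "perrin_prolate",
    "axial_ratio_prolate",
    "frictional_ratio",
    "stokes_radius_sphere",
]

AVOGADRO = 6.02214076e23
WATER_VISCOSITY_20C = 0.01002  # g/(cm s)
PARTIAL_SPECIFIC_VOLUME = 0.73  # mL/g, typical globular protein


@dataclass(frozen=True)
class CalibrationSeries:
    """Marker table: known physical values against observed positions.

    ``known`` may be molecular weights (kD), Stokes radii (Å) or Svedberg
    coefficients (S); ``positions`` are elution volumes (mL) or fraction
    indices.  At least two markers with strictly monotone positions are
    required.
    """

    names: tuple
    known: np.ndarray
    positions: np.ndarray
    unit: str = ""

    def __init__(self, names, known, positions, unit: str = ""):
        known = np.asarray(known, dtype=float)
        positions = np.asarray(positions, dtype=float)
        if len(known) < 2 or len(known) != len(positions):
            raise ValueError("need >= 2 markers with matching positions")
        d = np.diff(positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("marker positions must be strictly monotone")
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "known", known)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "unit", unit)


@dataclass(frozen=True)
class LinearCalibration:
    slope: float
    intercept: float
    r_squared: float
    position_range: tuple[float, float]

    def predict(self, position: float) -> float:
        return self.slope * float(position) + self.intercept

    def interpolate(self, position: float) -> tuple[float, bool]:
        """Predicted physical value and whether the position is in range.

        Positions outside the marker span are still predicted but flagged
        as extrapolation.
        """
        lo, hi = self.position_range
        within = lo <= float(position) <= hi
        return self.predict(position), within


def linear_calibration(series: CalibrationSeries) -> LinearCalibration:
    """Ordinary least-squares line of known value against observed position."""
    if np.allclose(series.known, series.known[0]):
        slope, intercept, r2 = 0.0, float(series.known[0]), 1.0
    else:
        fit = stats.linregress(series.positions, series.known)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    return LinearCalibration(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        position_range=(float(series.positions.min()), float(series.positions.max())),
    )


def alpha_from_standards(mw_kd, a_times_s, weights=None) -> float:
    """Siegel–Monty α as the origin-constrained slope of MW against a·s.

    Weighted least squares through the origin: α = Σw·MW·(as) / Σw·(as)².
    """
    mw = np.atleast_1d(np.asarray(mw_kd, dtype=float))
    x = np.atleast_1d(np.asarray(a_times_s, dtype=float))
    if len(mw) != len(x) or len(mw) == 0:
        raise ValueError("need matching non-empty MW and a*s arrays")
    if np.any(x <= 0) or np.any(mw <= 0):
        raise ValueError("standards must have positive MW and a*s")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * mw * x) / np.sum(w * x * x))


def mw_siegel_monty(a: float, s: float, alpha: float) -> float:
    """Native molecular weight (kD) from Stokes radius, Svedberg and α."""
    if a <= 0 or s <= 0 or alpha <= 0:
        raise ValueError("a, s and alpha must be positive")
    return float(alpha * a * s)


def perrin_prolate(p: float) -> float:
    """Perrin translational frictional ratio f/f0 of a prolate ellipsoid.

    ``p`` is the axial ratio (long/short semi-axis, >= 1).  With q = 1/p:

        f/f0 = sqrt(1 - q^2) / (q^(2/3) * ln[(1 + sqrt(1 - q^2)) / q])

    which tends to 1 as p -> 1 and grows monotonically with elongation.
    """
    p = float(p)
    if p < 1:
        raise ValueError("axial ratio must be >= 1")
    if p == 1.0:
        return 1.0
    q = 1.0 / p
    e = np.sqrt(1.0 - q * q)
    return float(e / (q ** (2.0 / 3.0) * np.log((1.0 + e) / q)))


def axial_ratio_prolate(f_ratio: float, p_max: float = 1e4) -> float:
    """Invert the Perrin prolate function: axial ratio from f/f0.

    Bisection on [1, p_max]; f/f0 below 1 is unphysical and rejected.
    """
    f_ratio = float(f_ratio)
    if f_ratio < 1.0:
        raise ValueError("frictional ratio must be >= 1")
    if f_ratio == 1.0:
        return 1.0
    if perrin_prolate(p_max) < f_ratio:
        raise ValueError(f"frictional ratio {f_ratio} exceeds range up to p={p_max}")
    return float(brentq(lambda p: perrin_prolate(p) - f_ratio, 1.0, p_max,
                        xtol=1e-12, rtol=1e-12))


def stokes_radius_sphere(mw_kd: float, vbar: float = PARTIAL_SPECIFIC_VOLUME) -> float:
    """Minimal (anhydrous-sphere) Stokes radius in Å for a given mass.

    R0 = (3 M vbar / (4 π N))^(1/3) with M in g/mol and vbar in mL/g.
    """
    if mw_kd <= 0:
        raise ValueError("molecular weight must be positive")
    m_grams = mw_kd * 1e3  # g/mol
    r_cm = (3.0 * m_grams * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)
    return float(r_cm * 1e8)  # cm -> Å


def frictional_ratio(a_angstrom: float, mw_kd: float,
                     vbar: float = PARTIAL_SPECIFIC_VOLUME) -> float:
    """f/f0 from the measured Stokes radius and the anhydrous-sphere radius."""
    r0 = stokes_radius_sphere(mw_kd, vbar)
    return float(a_angstrom / r0)


def hydro_report(a: float, s: float, alpha: float,
                 vbar: float = PARTIAL_SPECIFIC_VOLUME) -> dict:
    """Full sizing report: MW, frictional ratio and prolate axial ratio."""
    mw = mw_siegel_monty(a, s, alpha)
    fr = frictional_ratio(a, mw, vbar)
    out = {
        "stokes_radius_A": float(a),
        "svedberg_S": float(s),
        "alpha": float(alpha),
        "mw_kD": mw,
        "frictional_ratio": fr,
    }
    out["axial_ratio_prolate"] = axial_ratio_prolate(fr) if fr >= 1.0 else None
    return out
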