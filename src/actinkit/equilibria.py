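"""Binding equilibria for actin monomer / ligand systems.

All concentrations are in µM internally.  The central primitive is the
ligand-depletion ("quadratic") 1:1 binding isotherm: when the total receptor
concentration is comparable to the dissociation constant, the free-ligand
approximation fails and the complex concentration must be obtained as the
physical root of the mass-action quadratic

    (A0 - C) * (L0 - C) = Kd * C .

Fluorescence observation maps occupancy linearly onto signal (NBD- or
AEDANS-labelled actin reports complex formation as a fractional intensity
change).  Competitive and two-independent-site systems are solved exactly by
bracketed root finding on free actin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OneToOneSystem",
    "FluorescenceMap",
    "CompetitionSystem",
    "TwoSiteSystem",
    "complex_concentration",
    "predicted_signal",
    "competition_solve",
    "apparent_kd",
    "two_site_signal",
]


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
    return value


def _check_pos(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and positive, got {value!r}")
    return value


@dataclass(frozen=True)
class OneToOneSystem:
    """A 1:1 receptor-ligand equilibrium with ligand depletion.

    Parameters
    ----------
    A0 : total receptor (actin) concentration, µM
    L0 : total ligand concentration, µM
    Kd : dissociation constant, µM
    """

    A0: float
    L0: float
    Kd: float

    def __post_init__(self) -> None:
        _check_nonneg("A0", self.A0)
        _check_nonneg("L0", self.L0)
        _check_pos("Kd", self.Kd)


@dataclass(frozen=True)
class FluorescenceMap:
    """Linear map from fractional occupancy to observed fluorescence.

    ``F = F0 + dF * occupancy``; at zero occupancy the signal is the baseline
    ``F0`` and at full saturation it is ``F0 + dF``.
    """

    F0: float = 0.0
    dF: float = 1.0

    def __call__(self, occupancy) -> np.ndarray | float:
        return self.F0 + self.dF * np.asarray(occupancy, dtype=float)


@dataclass(frozen=True)
class CompetitionSystem:
    """Two ligands competing for the same site on monomeric actin.

    E and T are mutually exclusive binders (e.g. a capping-domain fragment
    versus thymosin β4); free actin partitions between A·E and A·T according
    to the two dissociation constants.
    """

    A0: float
    E0: float
    K_E: float
    T0: float
    K_T: float
    dF_E: float = 0.0
    dF_T: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg("A0", self.A0)
        _check_nonneg("E0", self.E0)
        _check_nonneg("T0", self.T0)
        _check_pos("K_E", self.K_E)
        _check_pos("K_T", self.K_T)


@dataclass(frozen=True)
class TwoSiteSystem:
    """Two ligands binding independent, non-overlapping sites on actin.

    No cooperativity: each ligand equilibrates with total actin through its
    own 1:1 depletion isotherm, and fluorescence increments are additive.
    """

    A0: float
    L1_0: float
    K1: float
    L2_0: float
    K2: float
    dF1: float = 0.0
    dF2: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg("A0", self.A0)
        _check_nonneg("L1_0", self.L1_0)
        _check_nonneg("L2_0", self.L2_0)
        _check_pos("K1", self.K1)
        _check_pos("K2", self.K2)


def complex_concentration(system: OneToOneSystem) -> float:
    """Equilibrium complex concentration (µM) of a 1:1 depletion system.

    Returns the physically meaningful root ``0 <= C <= min(A0, L0)`` of
    ``(A0 - C)(L0 - C) = Kd * C``, computed with the numerically stable
    form of the quadratic formula (avoids cancellation when Kd is small
    relative to the totals).
    """
    A0, L0, Kd = system.A0, system.L0, system.Kd
    if A0 == 0.0 or L0 == 0.0:
        return 0.0
    b = A0 + L0 + Kd
    disc = b * b - 4.0 * A0 * L0
    # disc >= (A0-L0)^2 + Kd^2 > 0 analytically; clip against roundoff
    root = np.sqrt(max(disc, 0.0))
    # smaller root via the stable conjugate form: 2*A0*L0 / (b + sqrt(disc))
    C = 2.0 * A0 * L0 / (b + root)
    return float(min(C, A0, L0))


def occupancy(system: OneToOneSystem) -> float:
    """Fraction of receptor bound, C/A0 (0 for A0 = 0)."""
    if system.A0 == 0.0:
        return 0.0
    return complex_concentration(system) / system.A0


def predicted_signal(system: OneToOneSystem, fmap: FluorescenceMap) -> float:
    """Observed fluorescence for a 1:1 system under a linear observation map."""
    if system.A0 <= 0:
        raise ValueError("predicted_signal requires A0 > 0")
    return float(fmap(occupancy(system)))


def competition_solve(system: CompetitionSystem) -> dict[str, float]:
    """Exact species concentrations for two mutually exclusive ligands.

    Solves for free actin ``a`` by bracketed root finding on the monotone
    conservation residual

        a + a*E0/(K_E + a) + a*T0/(K_T + a) - A0 = 0

    then recovers A·E and A·T from mass action.  Conservation laws hold to
    relative 1e-9 or a numeric error is raised.

    Returns a dict with keys ``free_actin``, ``AE``, ``AT``, ``free_E``,
    ``free_T`` (all µM).
    """
    A0, E0, K_E, T0, K_T = system.A0, system.E0, system.K_E, system.T0, system.K_T
    if A0 == 0.0:
        return {"free_actin": 0.0, "AE": 0.0, "AT": 0.0, "free_E": E0, "free_T": T0}

    def residual(a: float) -> float:
        return a + a * E0 / (K_E + a) + a * T0 / (K_T + a) - A0

    a = brentq(residual, 0.0, A0, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    AE = a * E0 / (K_E + a)
    AT = a * T0 / (K_T + a)
    out = {
        "free_actin": float(a),
        "AE": float(AE),
        "AT": float(AT),
        "free_E": float(E0 - AE),
        "free_T": float(T0 - AT),
    }
    scale = max(A0, E0, T0, 1.0)
    errs = (
        abs(a + AE + AT - A0),
        abs(out["free_E"] + AE - E0),
        abs(out["free_T"] + AT - T0),
    )
    if max(errs) > 1e-9 * scale:
        raise ArithmeticError(
            f"competition_solve conservation residual {max(errs):.3e} exceeds tolerance"
        )
    return out


def competition_signal(system: CompetitionSystem, F0: float = 0.0) -> float:
    """Fluorescence of a competition mixture with per-species increments."""
    if system.A0 <= 0:
        raise ValueError("competition_signal requires A0 > 0")
    sp = competition_solve(system)
    return float(
        F0
        + system.dF_E * sp["AE"] / system.A0
        + system.dF_T * sp["AT"] / system.A0
    )


def apparent_kd(K_T0: float, E0: float, K_E: float) -> float:
    """Apparent dissociation constant of T in the presence of competitor E.

    Classical linear competition correction ``K_app = K_T0 * (1 + E0/K_E)``,
    valid in the regime where total actin is small relative to both
    dissociation constants (free competitor ~ total competitor).
    """
    _check_pos("K_T0", K_T0)
    _check_nonneg("E0", E0)
    _check_pos("K_E", K_E)
    return float(K_T0 * (1.0 + E0 / K_E))


def competitor_kd_from_apparent(K_T0: float, K_app: float, E0: float) -> float:
    """Invert the apparent-Kd relation for the competitor's own constant.

    ``K_E = E0 / (K_app/K_T0 - 1)``; requires ``K_app > K_T0`` and ``E0 > 0``.
    """
    _check_pos("K_T0", K_T0)
    _check_pos("K_app", K_app)
    _check_pos("E0", E0)
    if K_app <= K_T0:
        raise ValueError("K_app must exceed K_T0 for a positive competitor Kd")
    return float(E0 / (K_app / K_T0 - 1.0))


def competition_report(K_T0: float, pairs, claimed_K_E: float | None = None,
                       rel_tol: float = 0.5) -> dict:
    """Invert apparent-Kd pairs for the competitor constant, with a cross-check.

    ``pairs`` is an iterable of (E0, K_app) measurements.  Each pair is
    inverted through ``K_E = E0/(K_app/K_T0 - 1)``.  When ``claimed_K_E`` is
    supplied (an independently quoted value for the competitor's constant),
    the report flags it as inconsistent if it deviates from the
    formula-implied mean by more than ``rel_tol`` relative — the formula's
    value is always the one reported.
    """
    rows = []
    for E0, K_app in pairs:
        rows.append(
            {
                "E0": float(E0),
                "K_app": float(K_app),
                "K_E": competitor_kd_from_apparent(K_T0, K_app, E0),
            }
        )
    mean_ke = float(np.mean([r["K_E"] for r in rows]))
    out = {"K_T0": float(K_T0), "pairs": rows, "K_E_mean": mean_ke}
    if claimed_K_E is not None:
        rel_dev = abs(claimed_K_E - mean_ke) / mean_ke
        out["claimed_K_E"] = float(claimed_K_E)
        out["claimed_K_E_relative_deviation"] = rel_dev
        out["claimed_K_E_consistent"] = bool(rel_dev <= rel_tol)
    return out


def two_site_signal(system: TwoSiteSystem, F0: float = 0.0) -> float:
    """Fluorescence of a two-independent-site system.

    Each site's occupancy comes from its own 1:1 depletion solve against the
    shared actin pool; increments are additive (no cooperativity), so at
    double saturation the signal is ``F0 + dF1 + dF2``.
    """
    if system.A0 <= 0:
        raise ValueError("two_site_signal requires A0 > 0")
    th1 = occupancy(OneToOneSystem(system.A0, system.L1_0, system.K1))
    th2 = occupancy(OneToOneSystem(system.A0, system.L2_0, system.K2))
    return float(F0 + system.dF1 * th1 + system.dF2 * th2)
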