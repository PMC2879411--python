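"""Seeded filament-end elongation kinetics and nucleotide-exchange models.

The elongation rate law is V = [seeds] * k+ * (C - Cc): initial growth from a
fixed number of free filament ends is linear in the free monomer
concentration above the critical concentration Cc of that end.  Two distinct
inhibition mechanisms act on this law:

* **capping** — the inhibitor binds the filament end itself (nanomolar Kcap,
  substoichiometric with respect to monomer); the normalized rate equals the
  fraction of ends left free, which is independent of total G-actin;
* **sequestration** — the inhibitor binds monomeric actin into an
  assembly-incompetent 1:1 complex (micromolar Kseq, stoichiometric with
  monomer); free monomer drops, so the half-inhibition point scales with
  total G-actin and the dose curve shifts right when A0 is raised.

That A0 dependence is the operational discriminator between the two
mechanisms (see :func:`discriminate_mechanism`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .equilibria import OneToOneSystem, complex_concentration
from . import fitting
from .fitting import FitError, FitResult, nls_fit

__all__ = [
    "ElongationAssay",
    "CappingModel",
    "SequestrationModel",
    "ExchangeModel",
    "RateTitration",
    "elongation_rate",
    "seeds_from_rate",
    "capping_curve",
    "sequestration_curve",
    "fit_kcap",
    "fit_kseq",
    "ic50",
    "discriminate_mechanism",
    "exchange_kobs",
    "exchange_trace",
    "fit_exchange_trace",
    "BARBED_CC_UM",
    "POINTED_CC_UM",
    "KPLUS_BARBED",
]

# canonical Mg-ATP-actin values; configurable per assay
BARBED_CC_UM = 0.1
POINTED_CC_UM = 0.6
KPLUS_BARBED = 10.0  # µM^-1 s^-1


@dataclass(frozen=True)
class ElongationAssay:
    """Context of a seeded elongation experiment.

    Parameters
    ----------
    end : "barbed" or "pointed"
    seeds0 : free-end concentration, nM
    A0 : total G-actin, µM
    Cc : critical concentration at this end, µM
    kplus : association rate constant, µM⁻¹ s⁻¹
    """

    end: str = "barbed"
    seeds0: float = 2.0
    A0: float = 2.0
    Cc: float | None = None
    kplus: float = KPLUS_BARBED

    def __post_init__(self):
        if self.end not in ("barbed", "pointed"):
            raise ValueError(f"end must be 'barbed' or 'pointed', got {self.end!r}")
        if self.Cc is None:
            object.__setattr__(
                self, "Cc", BARBED_CC_UM if self.end == "barbed" else POINTED_CC_UM
            )
        if self.seeds0 < 0 or self.kplus <= 0:
            raise ValueError("seeds0 must be >= 0 and kplus > 0")
        if not self.A0 > self.Cc >= 0:
            raise ValueError(f"need A0 > Cc >= 0, got A0={self.A0}, Cc={self.Cc}")


@dataclass(frozen=True)
class CappingModel:
    """End-capping equilibrium: Kcap (nM) against ends0 (nM) free ends."""

    Kcap: float
    ends0: float = 2.0

    def __post_init__(self):
        if self.Kcap <= 0:
            raise ValueError("Kcap must be positive")
        if self.ends0 < 0:
            raise ValueError("ends0 must be non-negative")


@dataclass(frozen=True)
class SequestrationModel:
    """Monomer sequestration: Kseq (µM) for the non-polymerizable complex."""

    Kseq: float

    def __post_init__(self):
        if self.Kseq <= 0:
            raise ValueError("Kseq must be positive")


@dataclass(frozen=True)
class ExchangeModel:
    """Nucleotide (εATP) exchange on G-actin with and without bound ligand.

    k_free/k_bound are the pseudo-first-order exchange rate constants on free
    and ligand-complexed monomer; the observed rate is the occupancy-weighted
    mixture.
    """

    k_free: float
    k_bound: float
    Kd: float
    A0: float

    def __post_init__(self):
        if self.k_free <= 0 or self.k_bound < 0:
            raise ValueError("k_free must be > 0 and k_bound >= 0")
        if self.Kd <= 0 or self.A0 <= 0:
            raise ValueError("Kd and A0 must be positive")


@dataclass
class RateTitration:
    """Normalized elongation rates versus inhibitor concentration.

    ``rates`` are % of the uninhibited control (100 at zero inhibitor);
    ``ligand`` shares units with the mechanism constant being fitted
    (nM for capping, µM for sequestration).
    """

    ligand: np.ndarray
    rates: np.ndarray
    assay: ElongationAssay
    rate_sd: np.ndarray | None = None
    ligand_unit: str = "uM"

    def ligand_nM(self) -> np.ndarray:
        return self.ligand * 1e3 if self.ligand_unit == "uM" else self.ligand

    def ligand_uM(self) -> np.ndarray:
        return self.ligand * 1e-3 if self.ligand_unit == "nM" else self.ligand

    def __post_init__(self):
        if self.ligand_unit not in ("nM", "uM"):
            raise ValueError(f"ligand_unit must be 'nM' or 'uM', got {self.ligand_unit!r}")
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rate_sd is not None:
            self.rate_sd = np.asarray(self.rate_sd, dtype=float)
        if self.ligand.shape != self.rates.shape:
            raise ValueError("ligand and rates must have the same shape")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        # raw input may overshoot the control slightly; clip to [0, 120]%
        self.rates = np.clip(self.rates, 0.0, 120.0)


def elongation_rate(assay: ElongationAssay, free_actin: float) -> float:
    """Initial elongation rate V = seeds0 * kplus * max(C - Cc, 0), nM/s."""
    return float(assay.seeds0 * assay.kplus * max(float(free_actin) - assay.Cc, 0.0))


def seeds_from_rate(V: float, C: float, Cc: float, kplus: float = KPLUS_BARBED) -> float:
    """Free-end (seed) concentration in nM from an observed initial rate."""
    if C <= Cc:
        raise ValueError(f"need C > Cc to invert the rate law (C={C}, Cc={Cc})")
    if V < 0:
        raise ValueError("rate must be non-negative")
    return float(V / (kplus * (C - Cc)))


def capping_curve(model: CappingModel, capper) -> np.ndarray:
    """Normalized rate (%) vs capper total, with end depletion.

    The fraction of free ends comes from the 1:1 depletion quadratic between
    ends0 and the capper; at ends0 << Kcap this reduces to the hyperbola
    ``100 / (1 + X/Kcap)``.
    """
    capper = np.atleast_1d(np.asarray(capper, dtype=float))
    if np.any(capper < 0):
        raise ValueError("capper concentrations must be non-negative")
    out = np.empty_like(capper)
    for i, x in enumerate(capper):
        if model.ends0 == 0.0:
            out[i] = 100.0 / (1.0 + x / model.Kcap)
            continue
        c = complex_concentration(OneToOneSystem(model.ends0, x, model.Kcap))
        out[i] = 100.0 * (model.ends0 - c) / model.ends0
    return out


def capping_curve_hyperbolic(model: CappingModel, capper) -> np.ndarray:
    """Legend-style simple hyperbola 100/(1 + X/Kcap), no end depletion."""
    capper = np.atleast_1d(np.asarray(capper, dtype=float))
    return 100.0 / (1.0 + capper / model.Kcap)


def sequestration_curve(model: SequestrationModel, assay: ElongationAssay, sequesterer) -> np.ndarray:
    """Normalized rate (%) vs sequesterer total (µM).

    Free G-actin from the 1:1 depletion quadratic (A0, S0, Kseq); the
    normalized rate is 100*(Afree - Cc)/(A0 - Cc), floored at 0 once free
    monomer drops below the critical concentration.
    """
    seq = np.atleast_1d(np.asarray(sequesterer, dtype=float))
    if np.any(seq < 0):
        raise ValueError("sequesterer concentrations must be non-negative")
    out = np.empty_like(seq)
    for i, s0 in enumerate(seq):
        c = complex_concentration(OneToOneSystem(assay.A0, s0, model.Kseq))
        afree = assay.A0 - c
        out[i] = 100.0 * max(afree - assay.Cc, 0.0) / (assay.A0 - assay.Cc)
    return out


def _check_titration(data: RateTitration):
    if len(data.ligand) < 5:
        raise FitError("need at least 5 titration points including a control")
    if not np.any(data.ligand == 0):
        raise FitError("titration must include a zero-inhibitor control point")
    span = data.rates.max() - data.rates.min()
    if span < 5.0:  # <5% dynamic range: constant cannot be identified
        raise FitError("flat titration: inhibition constant not identifiable")


def fit_kcap(data: RateTitration, seed: int = 0, n_boot: int = 500,
             depletion: bool = True) -> FitResult:
    """Fit the end-capping constant Kcap (nM) to a normalized rate titration.

    The capper grid is converted to nM so Kcap shares units with the assay's
    free-end concentration.
    """
    _check_titration(data)
    ends0 = data.assay.seeds0
    x_nM = data.ligand_nM()

    if depletion:
        def curve(x, kcap):
            return capping_curve(CappingModel(Kcap=kcap, ends0=ends0), x)
    else:
        def curve(x, kcap):
            return capping_curve_hyperbolic(CappingModel(Kcap=kcap, ends0=ends0), x)

    scale = _half_point_scale(x_nM, data.rates)
    starts = [np.array([s]) for s in fitting.log_starts(scale, n=5, decades=4)]
    return nls_fit(
        curve, x_nM, data.rates, ["Kcap"], starts,
        bounds=([1e-6], [1e9]), sd=data.rate_sd, seed=seed, n_boot=n_boot,
        model_name="capping",
    )


def fit_kseq(data: RateTitration, seed: int = 0, n_boot: int = 500) -> FitResult:
    """Fit the monomer-sequestration constant Kseq (µM) to a rate titration."""
    _check_titration(data)
    assay = data.assay
    x_uM = data.ligand_uM()

    def curve(x, kseq):
        return sequestration_curve(SequestrationModel(Kseq=kseq), assay, x)

    scale = max(_half_point_scale(x_uM, data.rates), 1e-3)
    starts = [np.array([s]) for s in fitting.log_starts(scale, n=5, decades=4)]
    return nls_fit(
        curve, x_uM, data.rates, ["Kseq"], starts,
        bounds=([1e-9], [1e6]), sd=data.rate_sd, seed=seed, n_boot=n_boot,
        model_name="sequestration",
    )


def _half_point_scale(ligand: np.ndarray, rates: np.ndarray) -> float:
    """Data-implied concentration scale: grid point nearest 50% of control."""
    idx = int(np.argmin(np.abs(rates - 50.0)))
    x = ligand[idx]
    if x <= 0:
        pos = ligand[ligand > 0]
        x = float(np.median(pos)) if len(pos) else 1.0
    return float(x)


def ic50(ligand, rates) -> float:
    """Inhibitor concentration at 50% of control, by linear interpolation.

    Requires the curve to cross 50%; raises ValueError otherwise.
    """
    ligand = np.asarray(ligand, dtype=float)
    rates = np.asarray(rates, dtype=float)
    order = np.argsort(ligand)
    ligand, rates = ligand[order], rates[order]
    below = rates <= 50.0
    if not below.any() or not (~below).any():
        raise ValueError("curve does not cross 50% of control on this grid")
    j = int(np.argmax(below))  # first grid point at/below 50%
    if j == 0:
        raise ValueError("curve starts below 50%; no bracketing control point")
    x0, x1 = ligand[j - 1], ligand[j]
    y0, y1 = rates[j - 1], rates[j]
    if y0 == y1:
        return float(x0)
    return float(x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0))


def discriminate_mechanism(
    pair: tuple[RateTitration, RateTitration], seed: int = 0
) -> dict:
    """Classify a pair of titrations at two G-actin concentrations.

    Fits a single shared constant jointly across both curves under each
    mechanism hypothesis (capping: one Kcap with each assay's ends0;
    sequestration: one Kseq with each assay's A0) and classifies by the
    lower joint residual sum of squares.  When the two joint RSS values
    agree within 5% relative the result is "ambiguous" — never a silent
    coin flip.  The IC50 shift ratio (IC50 at high A0 / IC50 at low A0) is
    reported as corroborating evidence: sequestration predicts a ratio
    tracking the A0 ratio, capping predicts ~1.
    """
    low, high = pair
    if low.assay.A0 == high.assay.A0:
        raise ValueError("mechanism discrimination needs two different A0 values")
    if low.assay.A0 > high.assay.A0:
        low, high = high, low

    # capping works in nM against free ends, sequestration in µM against the
    # G-actin pool; fit each hypothesis on the grid in its own natural unit
    x_nM = np.concatenate([low.ligand_nM(), high.ligand_nM()])
    x_uM = np.concatenate([low.ligand_uM(), high.ligand_uM()])
    y = np.concatenate([low.rates, high.rates])
    n_low = len(low.ligand)

    def joint_capping(xx, kcap):
        a = capping_curve(CappingModel(Kcap=kcap, ends0=low.assay.seeds0), xx[:n_low])
        b = capping_curve(CappingModel(Kcap=kcap, ends0=high.assay.seeds0), xx[n_low:])
        return np.concatenate([a, b])

    def joint_seq(xx, kseq):
        a = sequestration_curve(SequestrationModel(Kseq=kseq), low.assay, xx[:n_low])
        b = sequestration_curve(SequestrationModel(Kseq=kseq), high.assay, xx[n_low:])
        return np.concatenate([a, b])

    starts_nM = [np.array([s]) for s in
                 fitting.log_starts(_half_point_scale(x_nM[:n_low], low.rates), n=5, decades=4)]
    starts_uM = [np.array([s]) for s in
                 fitting.log_starts(max(_half_point_scale(x_uM[:n_low], low.rates), 1e-3),
                                    n=5, decades=4)]
    fit_cap = nls_fit(joint_capping, x_nM, y, ["Kcap"], starts_nM,
                      bounds=([1e-6], [1e9]), n_boot=0, model_name="capping-joint")
    fit_seq = nls_fit(joint_seq, x_uM, y, ["Kseq"], starts_uM,
                      bounds=([1e-9], [1e6]), n_boot=0, model_name="sequestration-joint")

    rss_cap, rss_seq = fit_cap.rss, fit_seq.rss
    ratio = abs(rss_cap - rss_seq) / max(min(rss_cap, rss_seq), 1e-300)
    if ratio < 0.05:
        call = "ambiguous"
    elif rss_cap < rss_seq:
        call = "capping"
    else:
        call = "sequestration"

    shift = None
    try:
        shift = ic50(high.ligand, high.rates) / ic50(low.ligand, low.rates)
    except ValueError:
        pass
    return {
        "classification": call,
        "rss_capping": rss_cap,
        "rss_sequestration": rss_seq,
        "rss_ratio": ratio,
        "ic50_shift_ratio": shift,
        "fit_capping": fit_cap,
        "fit_sequestration": fit_seq,
    }


def exchange_kobs(model: ExchangeModel, ligand0: float) -> float:
    """Observed pseudo-first-order εATP exchange rate at a ligand total.

    The bound fraction comes from the depletion quadratic (A0, ligand0, Kd);
    k_obs interpolates linearly between k_free and k_bound with occupancy.
    """
    if ligand0 < 0:
        raise ValueError("ligand concentration must be non-negative")
    c = complex_concentration(OneToOneSystem(model.A0, ligand0, model.Kd))
    fb = c / model.A0
    return float(fb * model.k_bound + (1.0 - fb) * model.k_free)


def exchange_trace(k_obs: float, amplitude: float, t) -> np.ndarray:
    """Single-exponential fluorescence rise F(t) = F_inf * (1 - exp(-k t))."""
    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    t = np.asarray(t, dtype=float)
    return amplitude * (1.0 - np.exp(-k_obs * t))


def fit_exchange_trace(t, signal, seed: int = 0, n_boot: int = 0) -> FitResult:
    """Recover (k_obs, amplitude) from an exchange time course."""
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    amp0 = max(float(signal.max()), 1e-12)
    # characteristic time from half-rise
    half = amp0 / 2.0
    above = signal >= half
    t_half = t[np.argmax(above)] if above.any() and above.argmax() > 0 else (
        t[len(t) // 2] if len(t) > 2 else 1.0
    )
    k0 = np.log(2.0) / max(float(t_half), 1e-9)
    starts = [np.array([k, amp0]) for k in fitting.log_starts(k0, n=5, decades=4)]
    return nls_fit(
        lambda tt, k, a: exchange_trace(k, a, tt), t, signal,
        ["k_obs", "amplitude"], starts,
        bounds=([1e-12, 0.0], [1e6, np.inf]), seed=seed, n_boot=n_boot,
        model_name="exchange-trace",
    )
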