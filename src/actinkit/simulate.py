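"""Seeded synthetic-data generators for every assay class the fitters consume.

Each generator evaluates the exact mechanistic model the corresponding
fitter assumes — the ligand-depletion binding isotherm, the capping or
sequestration rate model, the two-state exchange model, a latent calibration
line — and adds homoscedastic Gaussian noise whose standard deviation is a
fraction of the noiseless curve's dynamic range (default 2%).  A single
run-level integer seed fans out to per-replicate streams through NumPy's
SeedSequence spawning, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import FluorescenceMap, OneToOneSystem, predicted_signal
from .kinetics import (
    CappingModel,
    ElongationAssay,
    ExchangeModel,
    RateTitration,
    SequestrationModel,
    capping_curve,
    exchange_kobs,
    exchange_trace,
    sequestration_curve,
)

__all__ = [
    "TitrationCurve",
    "gen_titration",
    "gen_rate_titration",
    "gen_exchange",
    "gen_calibration",
    "DEFAULT_NOISE",
]

DEFAULT_NOISE = 0.02  # sd as fraction of the curve's dynamic range


@dataclass
class TitrationCurve:
    """One simulated fluorescence titration with its generating truth."""

    ligand: np.ndarray
    signal: np.ndarray
    signal_sd: np.ndarray
    truth: dict
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_conc_uM": self.ligand,
                "signal": self.signal,
                "signal_sd": self.signal_sd,
            }
        )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _add_noise(rng, curve: np.ndarray, noise: float) -> tuple[np.ndarray, float]:
    dyn = float(curve.max() - curve.min())
    sd = noise * dyn if dyn > 0 else noise * max(abs(curve).max(), 1.0)
    if sd == 0:
        return curve.copy(), 0.0
    return curve + rng.normal(0.0, sd, size=curve.shape), sd


def gen_titration(
    Kd: float,
    A0: float = 1.5,
    grid=None,
    fmap: FluorescenceMap | None = None,
    noise: float = DEFAULT_NOISE,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[TitrationCurve]:
    """Simulate NBD-style fluorescence titrations of a 1:1 depletion system.

    Defaults emulate the standard layout: 1.5 µM labelled actin titrated
    with ligand over a grid spanning the binding transition, baseline 100
    with a 20% increment at saturation.
    """
    if grid is None:
        grid = np.linspace(0.0, 10.0 * Kd + A0, 15)
    grid = np.asarray(grid, dtype=float)
    fmap = fmap or FluorescenceMap(F0=100.0, dF=20.0)
    model = np.array(
        [predicted_signal(OneToOneSystem(A0, L, Kd), fmap) for L in grid]
    )
    out = []
    for rng in _spawn_rngs(seed, n_replicates):
        y, sd = _add_noise(rng, model, noise)
        out.append(
            TitrationCurve(
                ligand=grid.copy(),
                signal=y,
                signal_sd=np.full_like(grid, sd),
                truth={"Kd": Kd, "A0": A0, "F0": fmap.F0, "dF": fmap.dF, "noise": noise},
                seed=seed,
            )
        )
    return out


def gen_rate_titration(
    mechanism: str,
    K: float,
    assay: ElongationAssay | None = None,
    grid=None,
    noise: float = DEFAULT_NOISE,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[RateTitration]:
    """Simulate normalized elongation-rate titrations.

    ``mechanism`` is "capping" (K in nM, against the assay's free ends) or
    "sequestration" (K in µM, against the assay's G-actin pool).  The
    control point is forced to exactly 100% after noise, matching how
    measured rates are normalized to the uninhibited control.
    """
    if mechanism not in ("capping", "sequestration"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if assay is None:
        assay = ElongationAssay(end="barbed") if mechanism == "capping" else ElongationAssay(end="pointed")
    if grid is None:
        grid = np.linspace(0.0, 10.0 * K, 12) if mechanism == "capping" else np.linspace(
            0.0, max(4.0 * K, 2.0 * assay.A0), 12
        )
    grid = np.asarray(grid, dtype=float)
    if mechanism == "capping":
        model = capping_curve(CappingModel(Kcap=K, ends0=assay.seeds0), grid)
    else:
        model = sequestration_curve(SequestrationModel(Kseq=K), assay, grid)
    out = []
    for rng in _spawn_rngs(seed, n_replicates):
        y, sd = _add_noise(rng, model, noise)
        y = np.clip(y, 0.0, None)
        y[grid == 0.0] = 100.0  # normalization pins the control
        out.append(
            RateTitration(
                ligand=grid.copy(),
                rates=y,
                assay=assay,
                rate_sd=np.full_like(grid, sd) if sd > 0 else None,
                ligand_unit="nM" if mechanism == "capping" else "uM",
            )
        )
    return out


def gen_exchange(
    model: ExchangeModel,
    ligand_grid,
    t_grid=None,
    amplitude: float = 1.0,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate εATP exchange time courses across a ligand titration.

    Returns one trace DataFrame (`time_s`, `signal`) per ligand
    concentration plus a table of the generating k_obs values.
    """
    ligand_grid = np.asarray(ligand_grid, dtype=float)
    kobs = np.array([exchange_kobs(model, L) for L in ligand_grid])
    if t_grid is None:
        # cover ~5 time constants of the slowest trace
        t_grid = np.linspace(0.0, 5.0 / kobs.min(), 60)
    t_grid = np.asarray(t_grid, dtype=float)
    traces = []
    for rng, k in zip(_spawn_rngs(seed, len(ligand_grid)), kobs):
        clean = exchange_trace(k, amplitude, t_grid)
        y, _ = _add_noise(rng, clean, noise)
        traces.append(pd.DataFrame({"time_s": t_grid, "signal": y}))
    table = pd.DataFrame({"ligand_conc_uM": ligand_grid, "k_obs_true": kobs})
    return traces, table


def gen_calibration(
    slope: float,
    intercept: float,
    positions,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
    names=None,
    unit: str = "",
):
    """Simulate a marker calibration series from a latent line.

    Known marker values are generated as ``slope*position + intercept`` plus
    range-scaled Gaussian noise, emulating a Svedberg- or Stokes-radius
    calibration table.
    """
    from .hydro import CalibrationSeries

    positions = np.asarray(positions, dtype=float)
    rng = np.random.default_rng(seed)
    clean = slope * positions + intercept
    known, _ = _add_noise(rng, clean, noise)
    if names is None:
        names = [f"marker{i+1}" for i in range(len(positions))]
    return CalibrationSeries(names=names, known=known, positions=positions, unit=unit)
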