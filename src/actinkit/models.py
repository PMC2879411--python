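"""Statsmodels-style model classes for the assay fitters.

Each model class wraps one mechanistic curve, is constructed from arrays or
a DataFrame, and ``fit()`` returns a :class:`TitrationResults` carrying the
estimates, asymptotic standard errors, seeded bootstrap confidence
intervals, residual diagnostics and a ``summary()`` table.

    >>> model = BindingTitration(ligand_uM, signal, A0=1.5)
    >>> res = model.fit(seed=1)
    >>> res.params["Kd"]

Functions in :mod:`actinkit.kinetics` (``fit_kcap``, ``fit_kseq``) and the
CLI are thin layers over these classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fitting
from .equilibria import FluorescenceMap, OneToOneSystem, predicted_signal
from .fitting import FitResult, nls_fit
from .kinetics import (
    CappingModel,
    ElongationAssay,
    RateTitration,
    SequestrationModel,
    capping_curve,
    capping_curve_hyperbolic,
    exchange_trace,
    sequestration_curve,
)

__all__ = [
    "TitrationResults",
    "BindingTitration",
    "CappingTitration",
    "SequestrationTitration",
    "ExchangeKinetics",
]


class TitrationResults:
    """Fit results with statsmodels-flavoured accessors.

    Attributes
    ----------
    params : pandas Series of point estimates
    bse : pandas Series of asymptotic standard errors
    rss : weighted residual sum of squares
    """

    def __init__(self, model, fit: FitResult):
        self.model = model
        self._fit = fit
        self.params = pd.Series(fit.params)
        self.bse = pd.Series(fit.stderr)
        self.rss = fit.rss
        self.nobs = fit.n_obs
        self.converged = fit.converged
        self.seed = fit.seed

    def conf_int(self) -> pd.DataFrame:
        """95% bootstrap interval per parameter (NaN without bootstrap)."""
        if not self._fit.ci:
            nan = float("nan")
            return pd.DataFrame(
                {"lower": [nan] * len(self.params), "upper": [nan] * len(self.params)},
                index=self.params.index,
            )
        lo = {k: v[0] for k, v in self._fit.ci.items()}
        hi = {k: v[1] for k, v in self._fit.ci.items()}
        return pd.DataFrame({"lower": pd.Series(lo), "upper": pd.Series(hi)})

    @property
    def resid(self) -> np.ndarray:
        return self._fit.residuals

    def predict(self, x=None) -> np.ndarray:
        x = self.model.exog if x is None else np.asarray(x, dtype=float)
        return self.model.curve(x, *self.params.values)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"{self.model.__class__.__name__} fit ({self._fit.model_name})",
            f"  n_obs = {self.nobs}, RSS = {self.rss:.6g}, converged = {self.converged}",
            f"  {'param':<12}{'estimate':>14}{'std err':>12}{'[2.5%':>12}{'97.5%]':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<12}{self.params[name]:>14.6g}{self.bse[name]:>12.4g}"
                f"{ci.loc[name, 'lower']:>12.4g}{ci.loc[name, 'upper']:>12.4g}"
            )
        if self._fit.at_bounds:
            lines.append(f"  at bounds: {', '.join(self._fit.at_bounds)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self._fit.to_dict()


class _TitrationModel:
    """Shared construction and fit plumbing for all titration models."""

    param_names: list[str] = []
    model_name: str = ""

    def __init__(self, exog, endog, sd=None):
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float)
        self.sd = None if sd is None else np.asarray(sd, dtype=float)
        if self.exog.shape != self.endog.shape:
            raise ValueError("exog and endog must have matching shapes")

    def curve(self, x, *params):  # pragma: no cover - abstract
        raise NotImplementedError

    def _starts(self) -> list[np.ndarray]:
        raise NotImplementedError

    def _bounds(self):
        return None

    def fit(self, seed: int = 0, n_boot: int = 500) -> TitrationResults:
        res = nls_fit(
            self.curve, self.exog, self.endog, self.param_names, self._starts(),
            bounds=self._bounds(), sd=self.sd, seed=seed, n_boot=n_boot,
            model_name=self.model_name,
        )
        return TitrationResults(self, res)


class BindingTitration(_TitrationModel):
    """Ligand-depletion 1:1 binding isotherm fitted to a fluorescence titration.

    Observed signal F(L0) = F0 + dF * C(A0, L0, Kd)/A0 with the complex
    concentration from the mass-action quadratic; fitted parameters are
    (Kd, F0, dF) with total actin A0 known from the assay.
    """

    param_names = ["Kd", "F0", "dF"]
    model_name = "binding-1to1-depletion"

    def __init__(self, ligand_uM, signal, A0: float, sd=None):
        super().__init__(ligand_uM, signal, sd=sd)
        if A0 <= 0:
            raise ValueError("A0 must be positive")
        self.A0 = float(A0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, A0: float) -> "BindingTitration":
        sd = df["signal_sd"].to_numpy() if "signal_sd" in df else None
        return cls(df["ligand_conc_uM"].to_numpy(), df["signal"].to_numpy(), A0, sd=sd)

    def curve(self, x, Kd, F0, dF):
        fmap = FluorescenceMap(F0=F0, dF=dF)
        return np.array(
            [predicted_signal(OneToOneSystem(self.A0, L, max(Kd, 1e-12)), fmap) for L in x]
        )

    def _starts(self):
        y = self.endog
        f0 = float(y[np.argmin(self.exog)])
        df0 = float(y.max() - y.min()) * np.sign(y[np.argmax(self.exog)] - f0 or 1.0)
        if df0 == 0:
            df0 = 1.0
        pos = self.exog[self.exog > 0]
        kscale = float(np.median(pos)) if len(pos) else 1.0
        return [np.array([k, f0, df0]) for k in fitting.log_starts(kscale, n=5, decades=4)]

    def _bounds(self):
        return ([1e-9, -np.inf, -np.inf], [1e6, np.inf, np.inf])


class CappingTitration(_TitrationModel):
    """Barbed-end capping titration: normalized rate vs capper (nM).

    One free parameter Kcap; the free-end concentration is taken from the
    assay context.  ``depletion=False`` selects the simple hyperbola
    100/(1 + X/Kcap) instead of the end-depletion quadratic.
    """

    param_names = ["Kcap"]
    model_name = "capping"

    def __init__(self, capper_nM, rates_pct, ends0_nM: float = 2.0, sd=None,
                 depletion: bool = True):
        super().__init__(capper_nM, rates_pct, sd=sd)
        self.ends0 = float(ends0_nM)
        self.depletion = depletion

    @classmethod
    def from_titration(cls, data: RateTitration, depletion: bool = True) -> "CappingTitration":
        return cls(data.ligand, data.rates, ends0_nM=data.assay.seeds0,
                   sd=data.rate_sd, depletion=depletion)

    def curve(self, x, Kcap):
        m = CappingModel(Kcap=max(Kcap, 1e-12), ends0=self.ends0)
        return capping_curve(m, x) if self.depletion else capping_curve_hyperbolic(m, x)

    def _starts(self):
        pos = self.exog[self.exog > 0]
        kscale = float(np.median(pos)) if len(pos) else 1.0
        return [np.array([k]) for k in fitting.log_starts(kscale, n=5, decades=4)]

    def _bounds(self):
        return ([1e-6], [1e9])


class SequestrationTitration(_TitrationModel):
    """Pointed-end sequestration titration: normalized rate vs ligand (µM)."""

    param_names = ["Kseq"]
    model_name = "sequestration"

    def __init__(self, ligand_uM, rates_pct, assay: ElongationAssay, sd=None):
        super().__init__(ligand_uM, rates_pct, sd=sd)
        self.assay = assay

    @classmethod
    def from_titration(cls, data: RateTitration) -> "SequestrationTitration":
        return cls(data.ligand, data.rates, data.assay, sd=data.rate_sd)

    def curve(self, x, Kseq):
        return sequestration_curve(SequestrationModel(Kseq=max(Kseq, 1e-12)), self.assay, x)

    def _starts(self):
        pos = self.exog[self.exog > 0]
        kscale = float(np.median(pos)) if len(pos) else 1.0
        return [np.array([k]) for k in fitting.log_starts(kscale, n=5, decades=4)]

    def _bounds(self):
        return ([1e-9], [1e6])


class ExchangeKinetics(_TitrationModel):
    """Single-exponential εATP exchange trace: F(t) = A(1 - exp(-k t))."""

    param_names = ["k_obs", "amplitude"]
    model_name = "exchange-trace"

    def __init__(self, time_s, signal, sd=None):
        super().__init__(time_s, signal, sd=sd)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExchangeKinetics":
        return cls(df["time_s"].to_numpy(), df["signal"].to_numpy())

    def curve(self, t, k_obs, amplitude):
        return exchange_trace(max(k_obs, 1e-12), amplitude, t)

    def _starts(self):
        amp0 = max(float(self.endog.max()), 1e-12)
        tspan = max(float(self.exog.max()), 1e-9)
        k0 = 3.0 / tspan
        return [np.array([k, amp0]) for k in fitting.log_starts(k0, n=5, decades=4)]

    def _bounds(self):
        return ([1e-12, 0.0], [1e6, np.inf])
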