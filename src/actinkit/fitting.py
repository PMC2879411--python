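"""Weighted nonlinear least-squares engine shared by all titration fitters.

Multi-start local least squares in log-parameter space (binding and kinetic
constants live on a decade scale, so log-space starts make the landscape
well conditioned), with a gradient-free Nelder-Mead fallback and seeded
case-resampling bootstrap confidence intervals.  All randomness flows from a
single integer seed, so identical data + seed gives a bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["FitResult", "nls_fit", "normalize_to_control", "bootstrap_ci", "FitError"]


class FitError(RuntimeError):
    """Raised when no start converges or the problem is not identifiable."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitResult:
    """Outcome of a weighted nonlinear least-squares fit.

    Attributes
    ----------
    params : dict of parameter name -> point estimate
    stderr : dict of parameter name -> asymptotic standard error (NaN when
        the Jacobian is rank deficient)
    ci : dict of parameter name -> (2.5%, 97.5%) bootstrap interval; empty
        when the fit was run without bootstrap resamples
    rss : residual sum of squares (weighted)
    residuals : weighted residual vector at the optimum
    converged : True when at least one start reached a local optimum
    n_obs : number of data points
    seed : seed used for bootstrap resampling (None when no bootstrap)
    model_name : label for reports
    at_bounds : names of parameters pinned at a box constraint
    """

    params: dict
    stderr: dict
    ci: dict
    rss: float
    residuals: np.ndarray
    converged: bool
    n_obs: int
    seed: int | None = None
    model_name: str = ""
    at_bounds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": {k: float(v) for k, v in self.params.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "ci95": {k: [float(lo), float(hi)] for k, (lo, hi) in self.ci.items()},
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "at_bounds": list(self.at_bounds),
            "seed": self.seed,
        }


def normalize_to_control(raw, control: float) -> np.ndarray:
    """Scale raw rates so the control value maps to 100 (% of control)."""
    if control == 0:
        raise ValueError("control value must be nonzero")
    return 100.0 * np.asarray(raw, dtype=float) / float(control)


def _weights_from_sd(sd, n: int) -> np.ndarray:
    if sd is None:
        return np.ones(n)
    sd = np.asarray(sd, dtype=float)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        return np.ones(n)
    return 1.0 / sd


def _single_start(func, x, y, w, p0, lb, ub):
    def wres(p):
        return w * (func(x, *p) - y)

    unbounded = np.all(np.isinf(lb)) and np.all(np.isinf(ub))
    if unbounded:
        # Levenberg-Marquardt reaches machine precision on well-posed problems
        return optimize.least_squares(wres, p0, method="lm", xtol=1e-15, ftol=1e-15,
                                      gtol=1e-15, max_nfev=2000)
    return optimize.least_squares(
        wres, p0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=2000,
    )


def nls_fit(
    func,
    x,
    y,
    param_names: list[str],
    starts: list[np.ndarray],
    bounds: tuple | None = None,
    sd=None,
    seed: int | None = None,
    n_boot: int = 0,
    model_name: str = "",
) -> FitResult:
    """Best-of-multi-start weighted least squares.

    Parameters
    ----------
    func : model curve ``func(x, *params) -> y``
    starts : list of start vectors (caller builds the log-spaced grid)
    bounds : (lower, upper) arrays; defaults to unbounded
    sd : per-point standard deviations; weights are 1/sd when given
    n_boot : number of case-resampling bootstrap replicates for the CI
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    npar = len(param_names)
    if len(y) < npar + 2:
        raise FitError(f"need at least {npar + 2} points to fit {npar} parameters")
    w = _weights_from_sd(sd, len(y))
    if bounds is None:
        lb = np.full(npar, -np.inf)
        ub = np.full(npar, np.inf)
    else:
        lb = np.asarray(bounds[0], dtype=float)
        ub = np.asarray(bounds[1], dtype=float)

    best = None
    diagnostics = []
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), lb, ub)
        try:
            res = _single_start(func, x, y, w, p0, lb, ub)
        except Exception as exc:  # singular Jacobian, overflow in model, ...
            diagnostics.append({"start": list(p0), "error": str(exc)})
            continue
        diagnostics.append({"start": list(p0), "cost": float(res.cost)})
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        # gradient-free fallback before giving up
        def sse(p):
            p = np.clip(p, lb, ub)
            r = w * (func(x, *p) - y)
            return float(r @ r)

        p0 = np.clip(starts[0], lb, ub)
        nm = optimize.minimize(sse, p0, method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
        if not nm.success:
            raise FitError("no start converged", diagnostics)
        popt = np.clip(nm.x, lb, ub)
        residuals = w * (func(x, *popt) - y)
        jac = None
    else:
        popt = best.x
        residuals = best.fun
        jac = best.jac

    popt, residuals, jac = _gauss_newton_polish(func, x, y, w, popt, lb, ub, jac, residuals)
    rss = float(residuals @ residuals)
    stderr = _asymptotic_stderr(jac, residuals, npar)
    at_bounds = [
        name
        for name, p, lo, hi in zip(param_names, popt, lb, ub)
        if np.isfinite(lo) and np.isclose(p, lo) or np.isfinite(hi) and np.isclose(p, hi)
    ]
    ci: dict = {}
    if n_boot > 0:
        ci = bootstrap_ci(
            func, x, y, param_names, popt, (lb, ub), sd=sd,
            n_resamples=n_boot, seed=0 if seed is None else seed,
        )
    return FitResult(
        params=dict(zip(param_names, map(float, popt))),
        stderr=dict(zip(param_names, stderr)),
        ci=ci,
        rss=rss,
        residuals=residuals,
        converged=True,
        n_obs=len(y),
        seed=seed,
        model_name=model_name,
        at_bounds=at_bounds,
    )


def _numeric_jacobian(func, x, w, p):
    npar = len(p)
    J = np.empty((len(x), npar))
    f0 = w * func(x, *p)
    for j in range(npar):
        # cube-root-of-eps step balances truncation against roundoff
        h = 6e-6 * max(abs(p[j]), 1e-3)
        pp = np.array(p, dtype=float)
        pm = np.array(p, dtype=float)
        pp[j] += h
        pm[j] -= h
        J[:, j] = (w * func(x, *pp) - w * func(x, *pm)) / (2 * h)
    return J


def _gauss_newton_polish(func, x, y, w, popt, lb, ub, jac, residuals, max_iter=4):
    """Refine the optimizer's solution to near machine precision.

    A few damped Gauss-Newton steps with a finite-difference Jacobian; on a
    linear model a single step lands exactly on the normal-equations
    solution.  Steps are only accepted when they reduce the cost and stay
    inside the bounds.
    """
    cost = float(residuals @ residuals)
    p = np.array(popt, dtype=float)
    for _ in range(max_iter):
        try:
            J = _numeric_jacobian(func, x, w, p)
            delta, *_ = np.linalg.lstsq(J, -residuals, rcond=None)
        except Exception:  # finite-difference probe outside the model's domain
            break
        p_new = np.clip(p + delta, lb, ub)
        r_new = w * (func(x, *p_new) - y)
        c_new = float(r_new @ r_new)
        if not np.isfinite(c_new) or c_new > cost * (1 + 1e-15):
            break
        step = float(np.max(np.abs(delta)))
        p, residuals, cost, jac = p_new, r_new, c_new, J
        if step <= 1e-12 * max(float(np.max(np.abs(p))), 1e-12):
            break
    return p, residuals, jac


def _asymptotic_stderr(jac, residuals, npar) -> list[float]:
    n = len(residuals)
    dof = max(n - npar, 1)
    s2 = float(residuals @ residuals) / dof
    if jac is None:
        return [float("nan")] * npar
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return [float(np.sqrt(max(v, 0.0))) for v in np.diag(cov)]
    except np.linalg.LinAlgError:
        return [float("nan")] * npar


def bootstrap_ci(
    func,
    x,
    y,
    param_names,
    popt,
    bounds,
    sd=None,
    n_resamples: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Case-resampling (pairs) bootstrap percentile intervals.

    Reproducible for a given seed; each resample is refit starting from the
    full-data optimum (a warm start keeps the resample fits cheap and
    deterministic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sd_arr = None if sd is None else np.asarray(sd, dtype=float)
    rng = np.random.default_rng(seed)
    lb, ub = bounds
    n = len(y)
    draws = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        wb = _weights_from_sd(None if sd_arr is None else sd_arr[idx], n)
        try:
            res = _single_start(func, xb, yb, wb, np.asarray(popt), lb, ub)
        except Exception:
            continue
        if res.success:
            draws.append(res.x)
    if len(draws) < max(10, n_resamples // 10):
        return {name: (float("nan"), float("nan")) for name in param_names}
    draws = np.asarray(draws)
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return {
        name: (float(l), float(h))
        for name, l, h in zip(param_names, lo, hi)
    }


def log_starts(center: float, n: int = 5, decades: float = 4.0) -> list[float]:
    """Log-spaced start values spanning ``decades`` around ``center``."""
    center = max(center, 1e-12)
    return list(np.geomspace(center * 10 ** (-decades / 2), center * 10 ** (decades / 2), n))
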