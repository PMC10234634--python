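"""Fit the delayed adaptation model to observed (⟨a⟩, ⟨τ⟩) trajectories.

The model takes the measured shear-rate trend ⟨τ⟩(t) as exogenous input,
filters it through the first-order sensing equation
dτs/dt = −(τs − ⟨τ⟩)/t_delay, and integrates the radius adaptation
d⟨a⟩/dt = (⟨a⟩/t_adapt)(τs²/τ0² − 1).  The free parameters are the
adaptation time t_adapt and the target shear τ0 (and optionally t_delay);
the objective is the relative L1 fitting error

    ε_err = (1/T_obs) ∫ |⟨a⟩ − ⟨a⟩_fit| / ⟨a⟩ dt ,

a dimensionless, unit-invariant measure of trajectory mismatch.

Usage follows the Model / Results convention::

    model = DelayedAdaptationModel(times, a_trend, tau_trend,
                                   delay_mode=120.0)
    res = model.fit()
    print(res.summary())
    a_hat = res.predict()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize

from .adaptation import AdaptationParams

__all__ = [
    "FitResult",
    "DelayedAdaptationModel",
    "DelayedAdaptationResults",
    "fitting_error",
    "forward_model",
    "fit_adaptation",
    "compare_delay_models",
]

# search bounds: t_adapt in [1, 1000] min, τ0 in (0.01, 100] 1/s,
# t_delay in [0, 15] min
BOUNDS = {
    "t_adapt_s": (60.0, 60000.0),
    "tau0": (0.01, 100.0),
    "t_delay_s": (0.0, 900.0),
}


def fitting_error(times: np.ndarray, a_obs: np.ndarray,
                  a_fit: np.ndarray) -> float:
    """Relative L1 error ε_err between observed and fitted radius series.

    Trapezoidal time average of |a − a_fit| / a; dimensionless.
    """
    times = np.asarray(times, dtype=float)
    a_obs = np.asarray(a_obs, dtype=float)
    a_fit = np.asarray(a_fit, dtype=float)
    if a_obs.shape != a_fit.shape or a_obs.shape != times.shape:
        raise ValueError("series must share one grid")
    if np.any(a_obs <= 0):
        raise ValueError("observed radius must be positive")
    rel = np.abs(a_obs - a_fit) / a_obs
    span = times[-1] - times[0]
    if span <= 0:
        return float(rel.mean())
    return float(np.trapezoid(rel, times) / span)


def _filter_first_order(times: np.ndarray, tau: np.ndarray,
                        t_delay: float, tau_s0: float) -> np.ndarray:
    """Exact exponential integrator for dτs/dt = −(τs − τ(t))/t_delay with
    piecewise-linear τ(t)."""
    if t_delay <= 0:
        return tau.copy()
    ts = np.empty_like(tau)
    ts[0] = tau_s0
    dt = np.diff(times)
    e = np.exp(-dt / t_delay)
    # over [t_i, t_i+1], τ(t) = τ_i + m (t − t_i):
    # τs(t_i+1) = τ_i+1 − m t_delay + (τs_i − τ_i + m t_delay) e
    m = np.diff(tau) / dt
    for i in range(dt.size):
        ts[i + 1] = (tau[i + 1] - m[i] * t_delay
                     + (ts[i] - tau[i] + m[i] * t_delay) * e[i])
    return ts


def forward_model(times: np.ndarray, tau: np.ndarray,
                  params: AdaptationParams, a0: float,
                  tau_s0: float | None = None) -> np.ndarray:
    """Integrate the model driven by a measured shear series.

    τs follows the sensing equation (exact exponential integrator on the
    piecewise-linear input); ⟨a⟩ then integrates in closed form,
    a(t) = a0 exp(∫ (τs²/τ0² − 1) dt / t_adapt), evaluated by trapezoidal
    quadrature on the data grid.
    """
    times = np.asarray(times, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if tau_s0 is None:
        tau_s0 = float(tau[0])
    ts = _filter_first_order(times, tau, params.t_delay_s, tau_s0)
    growth = ((ts / params.tau0) ** 2 - 1.0) / params.t_adapt_s
    log_a = np.concatenate(
        ([0.0], cumulative_trapezoid(growth, times)))
    return a0 * np.exp(log_a)


@dataclass
class FitResult:
    """Point estimates of one model fit."""

    t_adapt_s: float
    tau0: float
    t_delay_s: float
    delay_mode: str               # "fixed" or "free"
    eps_err: float
    converged: bool


class DelayedAdaptationModel:
    """Delayed shear-feedback adaptation model bound to one vein's data.

    Parameters
    ----------
    times, a_trend, tau_trend : common-grid trend series (s, μm, 1/s).
    delay_mode : "free" to fit t_delay, or a number of seconds to hold it
        fixed (e.g. the vein's cross-correlation estimate, or an ensemble
        mean).
    """

    def __init__(self, times, a_trend, tau_trend,
                 delay_mode: float | Literal["free"] = "free"):
        self.times = np.asarray(times, dtype=float)
        self.a = np.asarray(a_trend, dtype=float)
        self.tau = np.asarray(tau_trend, dtype=float)
        if not (self.times.shape == self.a.shape == self.tau.shape):
            raise ValueError("series must share one grid")
        if np.any(self.a <= 0):
            raise ValueError("radius trend must be positive")
        span = self.times[-1] - self.times[0]
        if span < 900.0:
            raise ValueError(
                f"trajectory covers {span:.0f} s; need >= 15 min to fit")
        self.delay_mode = delay_mode
        self.free_delay = delay_mode == "free"
        if not self.free_delay:
            self.fixed_delay = float(delay_mode)
            if not (BOUNDS["t_delay_s"][0] <= self.fixed_delay
                    <= BOUNDS["t_delay_s"][1]):
                raise ValueError("fixed t_delay outside bounds")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *,
                       time_col: str = "time_s", a_col: str = "a_um",
                       tau_col: str = "tau_per_s", **kw):
        return cls(df[time_col].to_numpy(), df[a_col].to_numpy(),
                   df[tau_col].to_numpy(), **kw)

    # -- objective ---------------------------------------------------------

    def _params(self, x: np.ndarray) -> AdaptationParams:
        # reported parameters always lie inside the search bounds
        t_adapt = float(np.exp(np.clip(x[0], *np.log(BOUNDS["t_adapt_s"]))))
        tau0 = float(np.exp(np.clip(x[1], *np.log(BOUNDS["tau0"]))))
        t_delay = (float(np.clip(x[2], *BOUNDS["t_delay_s"]))
                   if self.free_delay else self.fixed_delay)
        return AdaptationParams(
            t_adapt_s=t_adapt, tau0=tau0,
            t_delay_s=max(t_delay, 1e-9))

    def _eps_err(self, x: np.ndarray) -> float:
        lo, hi = np.log(BOUNDS["t_adapt_s"][0]), np.log(BOUNDS["t_adapt_s"][1])
        penalty = 0.0
        xc = x.copy()
        for i, key in enumerate(("t_adapt_s", "tau0")):
            lo, hi = np.log(BOUNDS[key][0]), np.log(BOUNDS[key][1])
            if not lo <= x[i] <= hi:
                penalty += 10.0 * (abs(x[i] - np.clip(x[i], lo, hi)) + 1.0)
                xc[i] = np.clip(x[i], lo, hi)
        if self.free_delay:
            lo, hi = BOUNDS["t_delay_s"]
            if not lo <= x[2] <= hi:
                penalty += 10.0 * (abs(x[2] - np.clip(x[2], lo, hi)) + 1.0)
                xc[2] = np.clip(x[2], lo, hi)
        p = self._params(xc)
        a_fit = forward_model(self.times, self.tau, p, self.a[0])
        if not np.all(np.isfinite(a_fit)):
            return 1e6 + penalty
        return fitting_error(self.times, self.a, a_fit) + penalty

    # -- fitting -----------------------------------------------------------

    def fit(self, n_starts: int = 8, xtol: float = 1e-4
            ) -> "DelayedAdaptationResults":
        """Multi-start Nelder–Mead minimisation of ε_err.

        Starts are laid out on a log-spaced grid over the (t_adapt, τ0)
        bounds, with τ0 centred on the observed shear scale.
        """
        tau_scale = float(np.median(np.abs(self.tau))) or 1.0
        tau_scale = min(max(tau_scale, BOUNDS["tau0"][0] * 1.5),
                        BOUNDS["tau0"][1] / 1.5)
        t_adapts = np.geomspace(300.0, 30000.0, max(2, n_starts // 2))
        tau0s = tau_scale * np.array([0.7, 1.4])
        starts = [(np.log(ta), np.log(t0))
                  for ta in t_adapts for t0 in tau0s][:n_starts]

        best = None
        for ta, t0 in starts:
            x0 = [ta, t0] + ([120.0] if self.free_delay else [])
            res = minimize(self._eps_err, np.array(x0), method="Nelder-Mead",
                           options={"xatol": xtol, "fatol": 1e-6,
                                    "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        p = self._params(best.x)
        eps = self._eps_err(best.x)
        result = FitResult(
            t_adapt_s=p.t_adapt_s, tau0=p.tau0, t_delay_s=p.t_delay_s,
            delay_mode="free" if self.free_delay else "fixed",
            eps_err=float(eps), converged=bool(best.success))
        return DelayedAdaptationResults(self, result)


class DelayedAdaptationResults:
    """Estimates, fit diagnostics and predictions of a fitted model."""

    def __init__(self, model: DelayedAdaptationModel, result: FitResult):
        self.model = model
        self._res = result

    @property
    def params(self) -> dict[str, float]:
        return {"t_adapt_s": self._res.t_adapt_s, "tau0": self._res.tau0,
                "t_delay_s": self._res.t_delay_s}

    @property
    def eps_err(self) -> float:
        return self._res.eps_err

    @property
    def converged(self) -> bool:
        return self._res.converged

    @property
    def result(self) -> FitResult:
        return self._res

    def predict(self, times=None, tau=None) -> np.ndarray:
        """Fitted radius trajectory (on the training grid by default)."""
        m = self.model
        t = m.times if times is None else np.asarray(times, dtype=float)
        x = m.tau if tau is None else np.asarray(tau, dtype=float)
        p = AdaptationParams(t_adapt_s=self._res.t_adapt_s,
                             tau0=self._res.tau0,
                             t_delay_s=max(self._res.t_delay_s, 1e-9))
        return forward_model(t, x, p, m.a[0])

    def summary(self) -> str:
        r = self._res
        lines = [
            "Delayed adaptation model fit",
            "=" * 44,
            f"{'n obs':<22}{self.model.times.size:>22d}",
            f"{'duration [min]':<22}"
            f"{(self.model.times[-1] - self.model.times[0]) / 60:>22.1f}",
            f"{'delay mode':<22}{r.delay_mode:>22}",
            "-" * 44,
            f"{'t_adapt [min]':<22}{r.t_adapt_s / 60:>22.2f}",
            f"{'tau0 [1/s]':<22}{r.tau0:>22.4g}",
            f"{'t_delay [min]':<22}{r.t_delay_s / 60:>22.2f}",
            f"{'eps_err':<22}{r.eps_err:>22.4g}",
            f"{'converged':<22}{str(r.converged):>22}",
            "=" * 44,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_adaptation(times, a_trend, tau_trend,
                   delay_mode: float | Literal["free"] = "free",
                   n_starts: int = 8) -> FitResult:
    """Fit (t_adapt, τ0[, t_delay]) to one trajectory; see
    :class:`DelayedAdaptationModel`."""
    model = DelayedAdaptationModel(times, a_trend, tau_trend,
                                   delay_mode=delay_mode)
    return model.fit(n_starts=n_starts).result


def compare_delay_models(times, a_trend, tau_trend, t_delay_s: float,
                         n_starts: int = 8
                         ) -> tuple[FitResult, FitResult]:
    """Two complete fits differing only in delay handling: with the given
    sensing delay versus the instantaneous model (t_delay = 0).

    Returns ``(with_delay, without_delay)``; on a near-constant trajectory
    both errors are ≈ 0 and the comparison is uninformative.
    """
    with_delay = fit_adaptation(times, a_trend, tau_trend,
                                delay_mode=t_delay_s, n_starts=n_starts)
    without = fit_adaptation(times, a_trend, tau_trend,
                             delay_mode=0.0, n_starts=n_starts)
    return with_delay, without
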