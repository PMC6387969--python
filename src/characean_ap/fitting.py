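"""Bounded least-squares estimation of model parameters from a PD trace.

Mirrors the manual tuning used to produce the fitted parameter columns:
local, bounded optimization from a user-supplied start against the full
simulator, with RMSE in mV as the goodness-of-fit proxy (the original fits
were judged by eye).  No global search is attempted or claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ArgumentError
from .parameters import ParameterSet, get_param, set_param
from .simulate import simulate_ap
from .traces import Trace

__all__ = ["FitSpec", "FitResult", "fit", "loss_profile"]

log = logging.getLogger(__name__)

# Starts already fitting to well below instrument noise are converged;
# residual at this level is solver tolerance, not signal.
_CONVERGED_AT_START_RMSE = 0.01  # mV


@dataclass(frozen=True)
class FitSpec:
    """Free parameters with bounds and starts, on top of a fixed base set.

    free maps parameter name -> (lower, upper, initial).  loss_windows, if
    given, restricts the RMSE to a union of time windows (s).
    """

    free: dict[str, tuple[float, float, float]]
    fixed: ParameterSet
    loss_windows: tuple[tuple[float, float], ...] | None = None
    max_evals: int = 200
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.free:
            raise ArgumentError("need at least one free parameter")
        for name, (lo, hi, x0) in self.free.items():
            get_param(self.fixed, name)  # validates the name/pump presence
            if not lo <= x0 <= hi:
                raise ArgumentError(
                    f"{name}: initial {x0} outside bounds [{lo}, {hi}]")


@dataclass
class FitResult:
    estimates: dict[str, float]
    loss: float                 # mV RMSE at the estimates
    n_evals: int
    converged: bool
    trace_fit: Trace | None     # None if the best point failed to re-simulate
    loss_initial: float = np.nan
    resample_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.loss < 0:
            raise ArgumentError("loss must be >= 0")


def _apply(ps: ParameterSet, names: list[str], x: np.ndarray) -> ParameterSet:
    for name, value in zip(names, x):
        ps = set_param(ps, name, float(value))
    return ps


def _loss_mask(trace: Trace, windows) -> np.ndarray:
    if windows is None:
        return np.ones(len(trace.t), dtype=bool)
    mask = np.zeros(len(trace.t), dtype=bool)
    for a, b in windows:
        mask |= (trace.t >= a) & (trace.t <= b)
    if not mask.any():
        raise ArgumentError("loss windows select no samples")
    return mask


def fit(trace: Trace, spec: FitSpec) -> FitResult:
    """Best bounded local minimum of trace RMSE from the given start.

    Deterministic given spec; a simulator failure at a queried point is
    logged and assigned a large residual rather than aborting the search.
    """
    names = list(spec.free)
    lo = np.array([spec.free[n][0] for n in names])
    hi = np.array([spec.free[n][1] for n in names])
    x0 = np.array([spec.free[n][2] for n in names])
    mask = _loss_mask(trace, spec.loss_windows)
    t_pre = max(0.0, -float(trace.t[0]))
    t_end = float(trace.t[-1])
    n_evals = 0

    def simulate(x: np.ndarray) -> np.ndarray | None:
        nonlocal n_evals
        n_evals += 1
        try:
            ps = _apply(spec.fixed, names, x)
            res = simulate_ap(ps, t_end=t_end, dt_out=trace.dt, t_pre=t_pre,
                              rtol=spec.sim_rtol, atol=spec.sim_atol)
        except Exception as exc:  # assigned infinite loss, not fatal
            log.warning("simulation failed at %s: %s",
                        dict(zip(names, x)), exc)
            return None
        return res.trace.v[:len(trace.v)]

    def residuals(x: np.ndarray) -> np.ndarray:
        v = simulate(x)
        if v is None:
            return np.full(int(mask.sum()), 1e3)
        return (v - trace.v)[mask]

    def rmse(r: np.ndarray) -> float:
        return float(np.sqrt(np.mean(r ** 2)))

    r0 = residuals(x0)
    loss0 = rmse(r0)
    if loss0 < _CONVERGED_AT_START_RMSE:
        v_fit = simulate(x0)
        return FitResult(estimates=dict(zip(names, x0)), loss=loss0,
                         n_evals=n_evals, converged=True,
                         trace_fit=Trace(trace.t.copy(), v_fit),
                         loss_initial=loss0)

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        diff_step=1e-3, x_scale=np.maximum(np.abs(x0), 1e-12),
                        ftol=1e-12, xtol=1e-12, gtol=1e-12,
                        max_nfev=spec.max_evals)
    x_best, r_best = sol.x, sol.fun
    if rmse(r_best) > loss0:  # never return worse than the start
        x_best, r_best = x0, r0
    v_fit = simulate(x_best)
    trace_fit = Trace(trace.t.copy(), v_fit) if v_fit is not None else None
    return FitResult(estimates={n: float(v) for n, v in zip(names, x_best)},
                     loss=rmse(r_best), n_evals=n_evals,
                     converged=bool(sol.success),
                     trace_fit=trace_fit,
                     loss_initial=loss0)


def loss_profile(trace: Trace, spec: FitSpec, name: str, *,
                 rel_span: float = 0.3, n_points: int = 13) -> np.ndarray:
    """1-D loss sweep ±rel_span around a parameter's initial value.

    Returns an (n_points, 2) array of (value, mV RMSE) with the other free
    parameters held at their initial values — an identifiability diagnostic
    that makes weakly constrained directions visible.
    """
    if name not in spec.free:
        raise ArgumentError(f"{name!r} is not a free parameter of the spec")
    names = list(spec.free)
    x0 = np.array([spec.free[n][2] for n in names])
    i = names.index(name)
    mask = _loss_mask(trace, spec.loss_windows)
    t_pre = max(0.0, -float(trace.t[0]))
    values = spec.free[name][2] * np.linspace(1 - rel_span, 1 + rel_span,
                                              n_points)
    out = np.empty((n_points, 2))
    for j, val in enumerate(values):
        x = x0.copy()
        x[i] = val
        ps = _apply(spec.fixed, names, x)
        try:
            res = simulate_ap(ps, t_end=float(trace.t[-1]), dt_out=trace.dt,
                              t_pre=t_pre, rtol=spec.sim_rtol,
                              atol=spec.sim_atol)
            r = (res.trace.v[:len(trace.v)] - trace.v)[mask]
            loss = float(np.sqrt(np.mean(r ** 2)))
        except Exception as exc:
            log.warning("profile point %s=%s failed: %s", name, val, exc)
            loss = np.inf
        out[j] = (val, loss)
    return out
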