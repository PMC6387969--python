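"""Coupled action-potential simulator.

Integrates the membrane voltage equation

    dV/dt = −(1/C_m)·[I_Cl + I_p + I_orc + I_bkg + I_TRP]

jointly with the five-variable store-excitation subsystem and the
first-order Cl⁻ gate, from the pre-excitation resting PD, with the IP₃
bolus applied at t = 0.  Time-varying schedules (κ_oi ramp, G_Cl,max decay)
and the ΔCa²⁺ square pulse partition the time axis; integration is split at
every such breakpoint so discontinuities never sit inside a solver step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import currents as cur
from .constants import mv_to_v, v_to_mv
from .errors import ArgumentError, IntegrationError
from .excitation import StoreState, _pump_term, _state_rates
from .parameters import ParameterSet
from .traces import Trace

__all__ = ["APResult", "simulate_ap", "resting_pd", "ap_rhs"]

resting_pd = cur.resting_pd  # zero-current PD, re-exported for convenience

_CURRENT_COLS = ("I_Cl", "I_p", "I_orc", "I_bkg", "I_TRP")


@dataclass
class APResult:
    """Simulation output: PD trace, state trajectory, per-current table."""

    trace: Trace
    states: pd.DataFrame    # t, x1..x5, y
    currents: pd.DataFrame  # t, I_Cl, I_p, I_orc, I_bkg, I_TRP, dVdt
    params: ParameterSet

    @property
    def peak_mV(self) -> float:
        return float(self.trace.v.max())


def _instantaneous(t: float, s: np.ndarray, ps: ParameterSet) -> dict:
    """All five currents (A·m⁻²) at one state sample."""
    x1, _, _, _, _, y, V = s
    kin, pas = ps.kinetics, ps.passive
    V_mV = v_to_mv(V)
    t_on, t_off = kin.dCa_window
    ts = max(t, 0.0)  # schedules and pulses run on post-bolus time
    y_c = min(max(y, 0.0), 1.0)

    if ps.schedule.gcl_decay is not None:
        g_cl = ps.schedule.gcl_decay.value(ts)
    else:
        g_cl = pas.G_Cl_max
    if ps.pump is not None:
        kappa = (ps.schedule.kappa_ramp.value(ts)
                 if ps.schedule.kappa_ramp is not None else ps.pump.kappa_oi)
        i_p = cur.pump_current(V_mV, ps.pump.replace(kappa_oi=kappa))
    else:
        i_p = 0.0

    return {
        "I_Cl": cur.chloride_current(V_mV, y_c, g_cl, pas.E_Cl),
        "I_p": i_p,
        "I_orc": cur.outward_rectifier_current(V_mV, pas),
        "I_bkg": cur.background_current(V_mV, pas.G_bkg, pas.E_bkg),
        "I_TRP": cur.trp_current(V_mV, ts if t >= 0 else -1.0, pas,
                                 (t_on, t_off)),
    }


def ap_rhs(t: float, s: np.ndarray, ps: ParameterSet) -> np.ndarray:
    """RHS of the full 7-state system [x1, x2..x5, y, V(volts)]."""
    x1, x2, x3, x4, x5, y, V = s
    kin, pas = ps.kinetics, ps.passive
    t_on, t_off = kin.dCa_window
    x1_eff = x1 + kin.dCa if (t_on <= t < t_off) else x1
    x1_eff = max(x1_eff, 0.0)
    I = kin.I0 * math.exp(-kin.ip3_decay * t) if t >= 0 else 0.0

    dx2, dx3, dx4, dx5 = _state_rates(x1_eff, x2, x3, x4, x5, I, kin)
    dx1 = (kin.lam * (kin.gamma0 + kin.gamma1 * x4) * (1.0 - x1_eff)
           - _pump_term(x1_eff, kin))
    y_c = min(max(y, 0.0), 1.0)
    # the Cl- gate responds to the Ca2+ elevation above rest (its rate
    # constants were measured for increased cytoplasmic Ca2+)
    ca_signal = max(x1_eff - kin.x1_rest, 0.0)
    dy = pas.k_a * ca_signal * (1.0 - y_c) - pas.k_i * y_c

    terms = _instantaneous(t, s, ps)
    dV = -sum(terms.values()) / pas.Cm
    return np.array([dx1, dx2, dx3, dx4, dx5, dy, dV])


def _breakpoints(ps: ParameterSet, t0: float, t1: float) -> list[float]:
    pts = {t0, t1}
    if t0 < 0.0 < t1:
        pts.add(0.0)
    kin = ps.kinetics
    if kin.dCa != 0.0 or ps.passive.G_Ca != 0.0:
        pts.update(kin.dCa_window)
    pts.update(ps.schedule.breakpoints())
    return sorted(p for p in pts if t0 <= p <= t1)


def simulate_ap(ps: ParameterSet, t_end: float = 20.0, dt_out: float = 0.01,
                *, t_pre: float = 0.0, initial_store: StoreState | None = None,
                rtol: float = 1e-8, atol: float = 1e-10,
                method: str = "LSODA") -> APResult:
    """Simulate a single AP; output is uniformly sampled at dt_out.

    ``t_pre`` > 0 prepends an unstimulated segment (no IP₃, no ΔCa²⁺, no
    TRP pulse) so pre-stimulus resting statistics can be read off the trace;
    its samples carry negative times.
    """
    if t_end <= 0 or dt_out <= 0:
        raise ArgumentError("t_end and dt_out must be > 0")
    if t_pre < 0:
        raise ArgumentError("t_pre must be >= 0")

    n_out = int(round((t_end + t_pre) / dt_out))
    t_grid = -t_pre + dt_out * np.arange(n_out + 1)
    kin = ps.kinetics
    if initial_store is None:
        initial_store = StoreState(x1=kin.x1_rest, x2=1.0, x3=0.0, x4=0.0,
                                   x5=0.0, t=float(t_grid[0]))
    y0 = np.array([initial_store.x1, initial_store.x2, initial_store.x3,
                   initial_store.x4, initial_store.x5, 0.0, mv_to_v(ps.V0)])

    out = np.empty((len(t_grid), 7))
    segs = _breakpoints(ps, float(t_grid[0]), float(t_grid[-1]))
    y = y0
    filled = 0
    for a, b in zip(segs[:-1], segs[1:]):
        last = b == segs[-1]
        mask = (t_grid >= a) & ((t_grid <= b) if last else (t_grid < b))
        t_eval = t_grid[mask]
        pts = t_eval if len(t_eval) and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(ap_rhs, (a, b), y, t_eval=pts, args=(ps,),
                        method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"AP solver failed on [{a}, {b}] s ({sol.message}); "
                f"state at segment start = {y.tolist()}")
        out[filled:filled + len(t_eval)] = sol.y[:, :len(t_eval)].T
        filled += len(t_eval)
        y = sol.y[:, -1]

    v_mV = v_to_mv(out[:, 6])
    trace = Trace(t=t_grid, v=v_mV, meta={
        "source": "simulation", "label": ps.label,
        "params_hash": ps.content_hash(), "rtol": rtol, "atol": atol,
        "dt_out": dt_out, "t_pre": t_pre})
    states = pd.DataFrame({
        "t": t_grid, "x1": out[:, 0], "x2": out[:, 1], "x3": out[:, 2],
        "x4": out[:, 3], "x5": out[:, 4], "y": out[:, 5]})

    rows = [_instantaneous(t, s, ps) for t, s in zip(t_grid, out)]
    currents = pd.DataFrame(rows)
    currents.insert(0, "t", t_grid)
    currents["dVdt"] = -currents[list(_CURRENT_COLS)].sum(axis=1) / ps.passive.Cm
    return APResult(trace=trace, states=states, currents=currents, params=ps)
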