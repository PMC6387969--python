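"""Small numerical utilities.

``fixed_step_rk4`` is a deliberately simple, scheme-independent integrator
used as an oracle against the adaptive solver: classical Runge-Kutta 4 with
a constant step.  Discontinuity times (pulse edges, schedule breakpoints)
should be multiples of dt so no step straddles them.
"""

from __future__ import annotations

import numpy as np

from .errors import ArgumentError

__all__ = ["fixed_step_rk4"]


def fixed_step_rk4(rhs, y0, t0: float, t1: float, dt: float,
                   t_eval=None, args: tuple = ()) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dy/dt = rhs(t, y, *args) with classical RK4.

    Returns (t_out, y_out) where t_out is ``t_eval`` (each entry must lie on
    the step grid within dt/2) or every step time.
    """
    if dt <= 0 or t1 <= t0:
        raise ArgumentError("need dt > 0 and t1 > t0")
    n_steps = int(round((t1 - t0) / dt))
    if abs(t0 + n_steps * dt - t1) > 1e-9:
        raise ArgumentError("(t1 - t0) must be a multiple of dt")
    y = np.asarray(y0, dtype=float).copy()

    if t_eval is None:
        idx = np.arange(n_steps + 1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        idx = np.round((t_eval - t0) / dt).astype(int)
        if np.any(np.abs(t0 + idx * dt - t_eval) > dt / 2) or np.any(
                (idx < 0) | (idx > n_steps)):
            raise ArgumentError("t_eval must lie on the RK4 step grid")
    want = np.full(n_steps + 1, False)
    want[idx] = True
    out = np.empty((int(want.sum()), len(y)))
    t_out = t0 + dt * np.flatnonzero(want)

    j = 0
    if want[0]:
        out[j] = y
        j += 1
    t = t0
    half = dt / 2.0
    for k in range(1, n_steps + 1):
        k1 = rhs(t, y, *args)
        k2 = rhs(t + half, y + half * k1, *args)
        k3 = rhs(t + half, y + half * k2, *args)
        k4 = rhs(t + dt, y + dt * k3, *args)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t0 + k * dt
        if want[k]:
            out[j] = y
            j += 1
    return t_out, out
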