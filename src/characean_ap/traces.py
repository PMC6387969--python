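"""Membrane-PD traces and the ensemble/tonoplast trace arithmetic.

A vacuolar electrode records the series sum of the plasma-membrane and
tonoplast PDs; the tonoplast AP is recovered by subtracting the averaged
plasma-membrane AP from the averaged both-membranes AP, with standard
deviations propagated in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ArgumentError

__all__ = ["Trace", "EnsembleTrace", "APFeatures", "ap_features",
           "average_traces", "subtract_tonoplast", "offset_trace"]

_UNIFORM_TOL = 1e-9


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise ArgumentError("trace needs at least two samples")
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ArgumentError(
            f"time must be strictly increasing; interval {i} "
            f"({t[i]} -> {t[i + 1]}) is not")
    step = float(dt[0])
    worst = int(np.argmax(np.abs(dt - step)))
    if abs(dt[worst] - step) > _UNIFORM_TOL:
        raise ArgumentError(
            f"non-uniform sampling: interval {worst} is {dt[worst]!r} s "
            f"vs step {step!r} s")
    return step


@dataclass
class Trace:
    """Uniformly sampled membrane-PD time series (t in s, v in mV)."""

    t: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ArgumentError("t and v must be 1-D arrays of equal length")
        _check_uniform(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def copy(self) -> "Trace":
        return Trace(self.t.copy(), self.v.copy(), dict(self.meta))


@dataclass
class EnsembleTrace:
    """Pointwise mean trace with pointwise SD band (NaN where undefined)."""

    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.t.shape == self.mean.shape == self.sd.shape):
            raise ArgumentError("t, mean, sd must share a shape")
        _check_uniform(self.t)
        if np.any(self.sd[np.isfinite(self.sd)] < 0):
            raise ArgumentError("sd must be >= 0")
        if self.n < 1:
            raise ArgumentError("n must be >= 1")

    def as_trace(self) -> Trace:
        return Trace(self.t.copy(), self.mean.copy(), {"kind": "ensemble mean",
                                                       "n": self.n})


@dataclass(frozen=True)
class APFeatures:
    """Scalar AP descriptors; NaN marks a feature the trace does not define."""

    peak: float
    t_peak: float
    duration: float
    half_width: float
    rest_pre: float
    rest_post: float


def _window_mean(tr: Trace, window: tuple[float, float]) -> float:
    a, b = window
    if b < a:
        raise ArgumentError(f"window must be ordered, got {window}")
    mask = (tr.t >= a - 1e-12) & (tr.t <= b + 1e-12)
    if not mask.any():
        raise ArgumentError(f"window {window} lies outside the trace span "
                            f"[{tr.t[0]}, {tr.t[-1]}]")
    return float(tr.v[mask].mean())


def _crossings(t: np.ndarray, v: np.ndarray, level: float) -> tuple[list, list]:
    """Linearly interpolated upward and downward crossing times of a level."""
    above = v > level
    up, down = [], []
    for i in range(len(v) - 1):
        if not above[i] and above[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            up.append(t[i] + f * (t[i + 1] - t[i]))
        elif above[i] and not above[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            down.append(t[i] + f * (t[i + 1] - t[i]))
    return up, down


def ap_features(tr: Trace, rest_window: tuple[float, float],
                post_window: tuple[float, float], *,
                guard_mV: float = 5.0) -> APFeatures:
    """Peak, timing, duration, half-width and resting levels of a single AP.

    duration runs from the first upward crossing of rest_pre + guard to the
    last downward crossing of rest_post + guard; half_width is the width of
    the interval where v exceeds the half-amplitude level
    (rest_pre + peak)/2.  Missing crossings yield NaN, never an exception.
    """
    rest_pre = _window_mean(tr, rest_window)
    rest_post = _window_mean(tr, post_window)
    i_peak = int(np.argmax(tr.v))
    peak = float(tr.v[i_peak])
    t_peak = float(tr.t[i_peak])

    half = 0.5 * (rest_pre + peak)
    up_h, down_h = _crossings(tr.t, tr.v, half)
    half_width = (down_h[-1] - up_h[0]) if (up_h and down_h) else math.nan

    up_d, _ = _crossings(tr.t, tr.v, rest_pre + guard_mV)
    _, down_d = _crossings(tr.t, tr.v, rest_post + guard_mV)
    duration = (down_d[-1] - up_d[0]) if (up_d and down_d) else math.nan

    return APFeatures(peak=peak, t_peak=t_peak, duration=duration,
                      half_width=half_width, rest_pre=rest_pre,
                      rest_post=rest_post)


def average_traces(traces: list[Trace], align: str = "stimulus") -> EnsembleTrace:
    """Pointwise mean and population SD over the aligned overlap region.

    align="stimulus" keeps every trace on its own clock (t = 0 is the
    stimulus); align="peak" shifts each trace so its maximum sits at t = 0.
    """
    if not traces:
        raise ArgumentError("need at least one trace")
    if align not in ("stimulus", "peak"):
        raise ArgumentError("align must be 'stimulus' or 'peak'")
    dt = traces[0].dt
    for tr in traces[1:]:
        if abs(tr.dt - dt) > _UNIFORM_TOL:
            raise ArgumentError("traces must share a sampling step")

    shifted = []
    for tr in traces:
        shift = tr.t[int(np.argmax(tr.v))] if align == "peak" else 0.0
        shifted.append((tr.t - shift, tr.v))

    t0 = max(t[0] for t, _ in shifted)
    t1 = min(t[-1] for t, _ in shifted)
    if t1 <= t0:
        raise ArgumentError("aligned traces have no overlap")
    rows = []
    for t, v in shifted:
        i0 = int(round((t0 - t[0]) / dt))
        n = int(round((t1 - t0) / dt)) + 1
        rows.append(v[i0:i0 + n])
    n_pts = min(len(r) for r in rows)
    block = np.vstack([r[:n_pts] for r in rows])
    t_out = t0 + dt * np.arange(n_pts)
    return EnsembleTrace(t=t_out, mean=block.mean(axis=0),
                         sd=block.std(axis=0, ddof=0), n=len(traces))


def subtract_tonoplast(both: EnsembleTrace, pm: EnsembleTrace) -> EnsembleTrace:
    """Tonoplast AP: both-membranes mean minus plasma-membrane mean.

    The shorter record is extended at its final (resting) mean value; SD is
    undefined (NaN) over the extension.  SDs combine in quadrature:
    sd = sqrt(sd_both² + sd_pm²).
    """
    if abs(both.t[1] - both.t[0] - (pm.t[1] - pm.t[0])) > _UNIFORM_TOL:
        raise ArgumentError("ensembles must share a sampling step")
    if abs(both.t[0] - pm.t[0]) > _UNIFORM_TOL:
        raise ArgumentError("ensembles must start on the same grid")
    dt = both.t[1] - both.t[0]
    n = max(len(both.t), len(pm.t))

    def extend(e: EnsembleTrace) -> tuple[np.ndarray, np.ndarray]:
        pad = n - len(e.t)
        if pad == 0:
            return e.mean, e.sd
        mean = np.concatenate([e.mean, np.full(pad, e.mean[-1])])
        sd = np.concatenate([e.sd, np.full(pad, np.nan)])
        return mean, sd

    mean_b, sd_b = extend(both)
    mean_p, sd_p = extend(pm)
    t_out = both.t[0] + dt * np.arange(n)
    return EnsembleTrace(t=t_out, mean=mean_b - mean_p,
                         sd=np.sqrt(sd_b ** 2 + sd_p ** 2),
                         n=min(both.n, pm.n))


def offset_trace(tr: Trace, dv: float) -> Trace:
    """Shift a trace by dv mV (e.g. +55 mV to move a vacuolar record onto
    the tonoplast scale)."""
    out = tr.copy()
    out.v = out.v + dv
    out.meta["offset_mV"] = out.meta.get("offset_mV", 0.0) + dv
    return out
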