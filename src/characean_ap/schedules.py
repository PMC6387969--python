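"""Time-varying parameter schedules.

Two slow modulations act during the AP besides the store kinetics:

* a piecewise-linear ramp of the pump rate constant κ_oi, representing
  transient inhibition of the H⁺ pump by elevated cytoplasmic Ca²⁺
  (optionally followed by a linear recovery);
* an exponential relaxation of the maximal Cl⁻ conductance G_Cl,max during
  the first seconds of excitation, seen in long saline exposures.

Both run on simulation time with t = 0 at the IP₃ bolus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ArgumentError

__all__ = ["KappaRamp", "GclDecay", "Schedule", "evaluate_schedule"]


@dataclass(frozen=True)
class KappaRamp:
    """Linear κ_oi ramp: constant start_value before t_start, linear to
    end_value at t_stop, then (if recovery_value is set) linear to
    recovery_value over recovery_duration, else held."""

    t_start: float
    t_stop: float
    start_value: float
    end_value: float
    recovery_value: Optional[float] = None
    recovery_duration: float = 2.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_stop:
            raise ArgumentError("ramp requires t_start < t_stop")
        for name in ("start_value", "end_value"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")
        if self.recovery_value is not None and self.recovery_value <= 0:
            raise ArgumentError("recovery_value must be > 0")

    def value(self, t: float) -> float:
        if t <= self.t_start:
            return self.start_value
        if t < self.t_stop:
            frac = (t - self.t_start) / (self.t_stop - self.t_start)
            return self.start_value + frac * (self.end_value - self.start_value)
        if self.recovery_value is None:
            return self.end_value
        t_rec = self.t_stop + self.recovery_duration
        if t < t_rec:
            frac = (t - self.t_stop) / self.recovery_duration
            return self.end_value + frac * (self.recovery_value - self.end_value)
        return self.recovery_value

    def breakpoints(self) -> list[float]:
        pts = [self.t_start, self.t_stop]
        if self.recovery_value is not None:
            pts.append(self.t_stop + self.recovery_duration)
        return pts


@dataclass(frozen=True)
class GclDecay:
    """Exponential G_Cl,max relaxation: G_end + (G_start − G_end)·e^(−t/tau)
    for t < duration, G_end afterwards."""

    G_start: float
    G_end: float
    duration: float = 5.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.G_start < 0 or self.G_end < 0:
            raise ArgumentError("conductances must be >= 0")
        if self.duration <= 0 or self.tau <= 0:
            raise ArgumentError("duration and tau must be > 0")

    def value(self, t: float) -> float:
        import math

        if t >= self.duration:
            return self.G_end
        return self.G_end + (self.G_start - self.G_end) * math.exp(-t / self.tau)

    def breakpoints(self) -> list[float]:
        return [self.duration]


@dataclass(frozen=True)
class Schedule:
    """Container for the optional κ_oi ramp and G_Cl,max decay."""

    kappa_ramp: Optional[KappaRamp] = None
    gcl_decay: Optional[GclDecay] = None

    def breakpoints(self) -> list[float]:
        pts: list[float] = []
        if self.kappa_ramp is not None:
            pts += self.kappa_ramp.breakpoints()
        if self.gcl_decay is not None:
            pts += self.gcl_decay.breakpoints()
        return pts


def evaluate_schedule(s: Schedule, t: float, kappa_oi0: float = None,
                      G_Cl_max0: float = None) -> tuple[float, float]:
    """(κ_oi, G_Cl,max) at time t.

    The fallback constants ``kappa_oi0`` / ``G_Cl_max0`` are returned for a
    component the schedule does not modulate.
    """
    if t < 0:
        raise ArgumentError("t must be >= 0")
    kappa = s.kappa_ramp.value(t) if s.kappa_ramp is not None else kappa_oi0
    gcl = s.gcl_decay.value(t) if s.gcl_decay is not None else G_Cl_max0
    return kappa, gcl
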