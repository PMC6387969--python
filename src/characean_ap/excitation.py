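"""Cytoplasmic Ca²⁺ and store-channel state dynamics.

The Ca²⁺ channel on the internal store has four states — unbound (R),
IP₃-bound (RI), conducting with an activating Ca²⁺ bound (RIC₊), and
inactivated with a second, inhibitory Ca²⁺ bound (RIC₊C₋).  Excitation is
initiated by a bolus of IP₃ that decays exponentially; the resulting opening
of store channels raises scaled cytoplasmic Ca²⁺ x₁ = C/C₀, which is pumped
back into the store through a Hill-type pump term.

State variables: x₁ (scaled Ca²⁺) and the channel-state fractions
x₂ (R), x₃ (RI), x₄ (RIC₊), x₅ (RIC₊C₋), which obey Σ x₂..₅ = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ArgumentError, IntegrationError

__all__ = [
    "StoreKinetics",
    "StoreState",
    "StoreTrajectory",
    "ip3_concentration",
    "store_state_derivatives",
    "calcium_derivative",
    "integrate_excitation",
    "equilibrium_x1",
    "equilibrium_state",
]

_CONSERVATION_TOL = 1e-8


@dataclass(frozen=True)
class StoreKinetics:
    """Kinetic constants of the store-channel / Ca²⁺ subsystem.

    Rates carrying a prime (k2_prime, k3_prime, p1_prime, p2_prime) are the
    unscaled values; the scaled coefficients used in the rate equations are
    k₂ = k₂′·C₀, k₃ = k₃′·C₀, p₁ = p₁′/C₀, p₂ = p₂′/C₀.

    Parameters
    ----------
    k1, k_m1 : float
        IP₃ binding/unbinding, (µM·s)⁻¹ and s⁻¹.
    k2_prime, k_m2 : float
        Activating Ca²⁺ binding/unbinding, (µM·s)⁻¹ and s⁻¹.
    k3_prime, k_m3 : float
        Inhibitory Ca²⁺ binding/unbinding, (µM·s)⁻¹ and s⁻¹; k₋₃ controls
        recovery from the inactivated state (refractoriness).
    gamma0, gamma1 : float
        Store permeability without IP₃ and density of IP₃-activated
        channels, s⁻¹.
    nu_r : float
        Store/cytoplasm volume ratio; λ = 1 + nu_r.
    C0 : float
        Average Ca²⁺ concentration scale, µM.
    p1_prime, p2_prime : float
        Store Ca²⁺-pump Hill parameters, µM·s⁻¹ and µM.
    hill_n : int
        Hill exponent of the pump (1 = Michaelis-Menten, 2 = cooperative).
    I0 : float
        IP₃ bolus injected at t = 0, µM.
    ip3_decay : float
        IP₃ decay rate, s⁻¹ (experimentally 0.2).
    dCa : float
        Dimensionless additive x₁ offset (TRP-like plasma-membrane Ca²⁺
        pulse), applied only inside ``dCa_window``.
    dCa_window : (float, float)
        On/off times of the ΔCa²⁺ pulse, s.
    x1_rest : float
        Initial scaled Ca²⁺, default 0.02/1.56 (resting cytoplasmic Ca²⁺
        over C₀).
    """

    k1: float = 12.0
    k_m1: float = 8.0
    k2_prime: float = 14.2
    k_m2: float = 1.595
    k3_prime: float = 1.51
    k_m3: float = 0.312
    gamma0: float = 0.1
    gamma1: float = 20.5
    nu_r: float = 0.185
    C0: float = 1.56
    p1_prime: float = 9.74
    p2_prime: float = 0.0197
    hill_n: int = 1
    I0: float = 2.1
    ip3_decay: float = 0.2
    dCa: float = 0.009
    dCa_window: tuple[float, float] = (0.07, 0.16)
    x1_rest: float = 0.02 / 1.56

    def __post_init__(self) -> None:
        for name in ("k1", "k_m1", "k2_prime", "k_m2", "k3_prime", "k_m3",
                     "gamma0", "gamma1", "nu_r", "C0", "p1_prime", "p2_prime",
                     "I0", "ip3_decay", "dCa", "x1_rest"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.C0 <= 0:
            raise ArgumentError("C0 must be positive")
        if self.hill_n not in (1, 2, 4):
            raise ArgumentError(f"hill_n must be 1, 2 or 4, got {self.hill_n}")
        t_on, t_off = self.dCa_window
        if t_off < t_on:
            raise ArgumentError(f"dCa_window must be ordered, got {self.dCa_window}")

    # scaled coefficients
    @property
    def lam(self) -> float:
        return 1.0 + self.nu_r

    @property
    def k2(self) -> float:
        return self.k2_prime * self.C0

    @property
    def k3(self) -> float:
        return self.k3_prime * self.C0

    @property
    def p1(self) -> float:
        return self.p1_prime / self.C0

    @property
    def p2(self) -> float:
        return self.p2_prime / self.C0

    def replace(self, **changes) -> "StoreKinetics":
        return replace(self, **changes)


@dataclass(frozen=True)
class StoreState:
    """Instantaneous store state: scaled Ca²⁺ and channel-state fractions."""

    x1: float
    x2: float
    x3: float
    x4: float
    x5: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0:
            raise ArgumentError(f"x1 must be >= 0, got {self.x1}")
        for name in ("x2", "x3", "x4", "x5"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ArgumentError(f"{name} must lie in [0, 1], got {v}")
        total = self.x2 + self.x3 + self.x4 + self.x5
        if abs(total - 1.0) > _CONSERVATION_TOL:
            raise ArgumentError(
                f"channel-state fractions must sum to 1 (got {total!r})")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.x2, self.x3, self.x4, self.x5)


@dataclass
class StoreTrajectory:
    """Excitation-only trajectory on a user grid (columns t, x1..x5)."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), 5): columns x1..x5
    kinetics: StoreKinetics = field(repr=False, default=None)

    @property
    def x1(self) -> np.ndarray:
        return self.x[:, 0]

    def fraction(self, k: int) -> np.ndarray:
        """Channel-state fraction x_k, k in {2,..,5}."""
        if k not in (2, 3, 4, 5):
            raise ArgumentError("fraction index must be 2..5")
        return self.x[:, k - 1]

    def conservation_error(self) -> np.ndarray:
        return np.abs(self.x[:, 1:].sum(axis=1) - 1.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "x1": self.x[:, 0], "x2": self.x[:, 1],
             "x3": self.x[:, 2], "x4": self.x[:, 3], "x5": self.x[:, 4]})


def ip3_concentration(I0: float, t: float, decay: float = 0.2):
    """IP₃ concentration (µM) at time t after a bolus I0: I0·exp(−decay·t)."""
    if np.any(np.asarray(t) < 0):
        raise ArgumentError("t must be >= 0")
    if I0 < 0:
        raise ArgumentError("I0 must be >= 0")
    return I0 * np.exp(-decay * np.asarray(t, dtype=float))


def _state_rates(x1: float, x2: float, x3: float, x4: float, x5: float,
                 I: float, kin: StoreKinetics) -> tuple[float, float, float, float]:
    k2, k3 = kin.k2, kin.k3
    dx2 = -kin.k1 * I * x2 + kin.k_m1 * x3
    dx3 = kin.k1 * I * x2 - (kin.k_m1 + k2 * x1) * x3 + kin.k_m2 * x4
    dx4 = k2 * x1 * x3 + kin.k_m3 * x5 - (kin.k_m2 + k3 * x1) * x4
    dx5 = k3 * x1 * x4 - kin.k_m3 * x5
    return dx2, dx3, dx4, dx5


def store_state_derivatives(state: StoreState, I: float,
                            kin: StoreKinetics) -> tuple[float, float, float, float]:
    """Rates (dx₂, dx₃, dx₄, dx₅)/dt in s⁻¹; their sum is 0 by conservation."""
    return _state_rates(state.x1, state.x2, state.x3, state.x4, state.x5, I, kin)


def _pump_term(x1: float, kin: StoreKinetics) -> float:
    # The pump re-sequesters Ca2+ in excess of the homeostatic resting
    # level x1_rest; the fitted p2' sits at the resting concentration, so a
    # pump acting on total Ca2+ would run near half-maximum at rest,
    # destabilizing the pre-stimulus baseline and quenching excitation.
    n = kin.hill_n
    excess = max(x1 - kin.x1_rest, 0.0)
    xn = excess ** n
    return kin.p1 * xn / (kin.p2 ** n + xn)


def calcium_derivative(x1: float, x4: float, kin: StoreKinetics) -> float:
    """dx₁/dt = λ(γ₀ + γ₁x₄)(1−x₁) − p₁·δⁿ/(p₂ⁿ + δⁿ), s⁻¹.

    The first term is release from the store (leak plus IP₃-activated
    channels in the conducting state x₄); the Hill ratio is the store
    Ca²⁺ pump re-sequestering the Ca²⁺ elevation δ = max(x₁ − x₁_rest, 0)
    above the homeostatic resting level.
    """
    if x1 < 0:
        raise ArgumentError(f"x1 must be >= 0, got {x1}")
    if not 0 <= x4 <= 1:
        raise ArgumentError(f"x4 must lie in [0, 1], got {x4}")
    return kin.lam * (kin.gamma0 + kin.gamma1 * x4) * (1.0 - x1) - _pump_term(x1, kin)


def excitation_rhs(t: float, s: np.ndarray, kin: StoreKinetics) -> np.ndarray:
    """RHS of the 5-state excitation subsystem [x1, x2..x5].

    During the ΔCa²⁺ window the effective x₁ (state value plus the constant
    pulse offset) is fed to every consumer of x₁.
    """
    x1, x2, x3, x4, x5 = s
    t_on, t_off = kin.dCa_window
    x1_eff = x1 + kin.dCa if (t_on <= t < t_off) else x1
    x1_eff = max(x1_eff, 0.0)
    I = kin.I0 * math.exp(-kin.ip3_decay * t)
    dx2, dx3, dx4, dx5 = _state_rates(x1_eff, x2, x3, x4, x5, I, kin)
    dx1 = (kin.lam * (kin.gamma0 + kin.gamma1 * x4) * (1.0 - x1_eff)
           - _pump_term(x1_eff, kin))
    return np.array([dx1, dx2, dx3, dx4, dx5])


def _breakpoints(kin: StoreKinetics, t0: float, t1: float) -> list[float]:
    pts = {t0, t1}
    if kin.dCa != 0.0:
        for tb in kin.dCa_window:
            if t0 < tb < t1:
                pts.add(tb)
    return sorted(pts)


def integrate_excitation(kin: StoreKinetics, t_grid: np.ndarray,
                         initial: StoreState | None = None,
                         rtol: float = 1e-8, atol: float = 1e-10,
                         method: str = "LSODA") -> StoreTrajectory:
    """Integrate the excitation subsystem over a strictly increasing grid.

    The IP₃ bolus is applied at t = 0 and decays exponentially; the ΔCa²⁺
    square pulse offsets x₁ inside its window.  Integration is split at the
    pulse edges so the discontinuity never sits inside a solver step.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ArgumentError("t_grid must be strictly increasing with >= 2 points")
    if initial is None:
        initial = StoreState(x1=kin.x1_rest, x2=1.0, x3=0.0, x4=0.0, x5=0.0,
                             t=float(t_grid[0]))
    y = np.array([initial.x1, initial.x2, initial.x3, initial.x4, initial.x5])
    out = np.empty((len(t_grid), 5))
    segs = _breakpoints(kin, float(t_grid[0]), float(t_grid[-1]))
    filled = 0
    for a, b in zip(segs[:-1], segs[1:]):
        mask = (t_grid >= a) & (t_grid <= b) if b == segs[-1] else \
               (t_grid >= a) & (t_grid < b)
        t_eval = t_grid[mask]
        pts = t_eval if len(t_eval) and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(excitation_rhs, (a, b), y, t_eval=pts,
                        args=(kin,), method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"excitation solver failed on [{a}, {b}]: {sol.message}; "
                f"state at failure start = {y.tolist()}")
        out[filled:filled + len(t_eval)] = sol.y[:, :len(t_eval)].T
        filled += len(t_eval)
        y = sol.y[:, -1]
    return StoreTrajectory(t=t_grid, x=out, kinetics=kin)


def equilibrium_x1(kin: StoreKinetics) -> float:
    """Resting fixed point of dx₁/dt with all channels unbound (x₄ = 0).

    Sits marginally above x1_rest, where the basal leak λγ₀ balances the
    pump acting on the excess.
    """
    f = lambda x1: calcium_derivative(x1, 0.0, kin)
    return brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-15)


def equilibrium_state(kin: StoreKinetics) -> StoreState:
    """Pre-stimulus fixed point: x₂ = 1 (all channels unbound), x₁ at rest."""
    return StoreState(x1=equilibrium_x1(kin), x2=1.0, x3=0.0, x4=0.0, x5=0.0)
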