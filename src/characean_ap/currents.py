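"""Plasma-membrane current sub-models and the zero-current resting PD.

Five currents enter the voltage equation (outward positive, depolarization =
V rising toward 0):

* ``chloride_current``   — Ca²⁺-activated Cl⁻ current, G_Cl·y·(V − E_Cl),
  gated by a first-order open fraction y driven by scaled cytoplasmic Ca²⁺;
* ``pump_current``       — H⁺-ATPase modeled as charge transit across a
  symmetric Eyring barrier (voltage-dependent k_io, k_oi) combined with
  voltage-independent cycle steps (κ_oi, κ_io);
* ``outward_rectifier_current`` — K⁺ GHK constant-field flux multiplied by
  Boltzmann open probabilities P_o+·P_o−;
* ``background_current`` — empirical ohmic leak G_bkg·(V − E_bkg);
* ``trp_current``        — TRP-like Ca²⁺ inflow, a square pulse in time with
  ohmic driving force G_Ca·(V − E_Ca).

``resting_pd`` solves I_p + I_bkg + I_orc = 0 by bisection with the Cl⁻ gate
closed and no TRP pulse — the model's pre-excitation steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .constants import (DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT, mv_to_v,
                        thermal_voltage, um_to_mol_m3, v_to_mv)
from .errors import ArgumentError, RootFindingError

__all__ = [
    "PumpParams", "PassiveParams", "GateState",
    "nernst_potential", "pump_current", "background_current",
    "outward_rectifier_current", "chloride_gate_derivative",
    "chloride_current", "trp_current", "resting_pd", "total_resting_current",
]


@dataclass(frozen=True)
class PumpParams:
    """Eyring-barrier H⁺ pump parameters.

    kappa_oi / kappa_io are the voltage-independent cycle rate constants
    (ATP/ADP/Pi/H⁺ binding, carrier recycling); kio0 / koi0 the barrier
    transit rates at 0 PD.  An absent pump is represented by pump=None at
    the parameter-set level, never by zeroed rates.
    """

    kappa_oi: float
    kio0: float
    koi0: float = 0.1
    kappa_io: float = 0.1
    z_p: float = 1.0
    N: float = 2e-8  # mol m^-2 scaling
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("kappa_oi", "kio0", "koi0", "kappa_io"):
            if getattr(self, name) <= 0:
                raise ArgumentError(
                    f"active pump requires {name} > 0 (got {getattr(self, name)}); "
                    "represent an inactive pump by pump=None")

    def replace(self, **changes) -> "PumpParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PassiveParams:
    """Passive-transporter parameters and ionic concentrations.

    Concentrations are mol·m⁻³ (= mM) except Ca_cyt which follows the
    tables' µM convention.  E_bkg, V50_plus, V50_minus in mV.
    """

    G_bkg: float = 0.5            # S m^-2
    E_bkg: float = -100.0         # mV
    NK_PK: float = 6.5e-7         # m^3 s^-1, channel count x permeability
    z: float = 1.0                # K+ valence
    z_g: float = 1.0              # gating charges
    V50_plus: float = 100.0       # mV
    # V50_minus is never printed; +300 mV puts the P_o- closure far above
    # the physiological range so P_o- ~ 1 there (P_o+ alone gates at rest).
    V50_minus: float = 300.0      # mV
    K_cyt: float = 80.0           # mol m^-3
    K_out: float = 0.1
    Cl_cyt: float = 60.0
    Cl_out: float = 1.3
    Ca_cyt: float = 0.02          # uM
    Ca_out: float = 0.1           # mol m^-3
    G_Cl_max: float = 4.0         # S m^-2
    k_a: float = 4.6              # s^-1, Cl- gate activation by Ca2+
    k_i: float = 2.0              # s^-1, Cl- gate inactivation
    G_Ca: float = 0.0             # S m^-2, TRP-like conductance
    Cm: float = 0.01              # F m^-2

    def __post_init__(self) -> None:
        for name in ("K_cyt", "K_out", "Cl_cyt", "Cl_out", "Ca_cyt", "Ca_out"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")
        for name in ("G_bkg", "G_Cl_max", "G_Ca", "NK_PK", "k_a", "k_i"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        if self.Cm <= 0:
            raise ArgumentError("Cm must be > 0")

    @property
    def E_Cl(self) -> float:
        """Cl⁻ reversal potential, mV."""
        return nernst_potential(self.Cl_cyt, self.Cl_out, -1)

    @property
    def E_K(self) -> float:
        """K⁺ reversal potential, mV."""
        return nernst_potential(self.K_cyt, self.K_out, +1)

    @property
    def E_Ca(self) -> float:
        """Ca²⁺ reversal potential, mV (Ca_cyt µM → mol·m⁻³)."""
        return nernst_potential(um_to_mol_m3(self.Ca_cyt), self.Ca_out, +2)

    def replace(self, **changes) -> "PassiveParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class GateState:
    """Open fraction of the Ca²⁺-activated Cl⁻ channel population."""

    y: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise ArgumentError(f"gate open fraction must lie in [0, 1], got {self.y}")


def nernst_potential(c_in: float, c_out: float, z: float,
                     T: float = DEFAULT_TEMPERATURE) -> float:
    """Nernst equilibrium potential (RT/zF)·ln(c_out/c_in) in mV."""
    if c_in <= 0 or c_out <= 0:
        raise ArgumentError("concentrations must be positive")
    return v_to_mv(thermal_voltage(T) / z * math.log(c_out / c_in))


def pump_current(V_mV: float, p: PumpParams) -> float:
    """H⁺ pump current in A·m⁻², positive outward.

    I_p = z_p·F·N·(k_io·κ_oi − k_oi·κ_io)/(k_io + k_oi + κ_io + κ_oi) with
    k_io = k_io⁰·exp(z_pFV/2RT) and k_oi = k_oi⁰·exp(−z_pFV/2RT).
    """
    u = p.z_p * mv_to_v(V_mV) / (2.0 * thermal_voltage(p.temperature))
    k_io = p.kio0 * math.exp(u)
    k_oi = p.koi0 * math.exp(-u)
    num = k_io * p.kappa_oi - k_oi * p.kappa_io
    den = k_io + k_oi + p.kappa_io + p.kappa_oi
    return p.z_p * FARADAY * p.N * num / den


def background_current(V_mV: float, G_bkg: float, E_bkg_mV: float = -100.0) -> float:
    """Empirical ohmic background current G_bkg·(V − E_bkg), A·m⁻²."""
    if G_bkg < 0:
        raise ArgumentError("G_bkg must be >= 0")
    return G_bkg * mv_to_v(V_mV - E_bkg_mV)


def outward_rectifier_current(V_mV: float, p: PassiveParams,
                              T: float = DEFAULT_TEMPERATURE) -> float:
    """Depolarization-activated K⁺ current, A·m⁻².

    GHK constant-field flux scaled by the Boltzmann open probabilities
    P_o+ and P_o−; the V = 0 removable singularity is evaluated by its
    analytic limit N_K·P_K·zF·P_o+·P_o−·([K]ᵢ − [K]ₒ).
    """
    vt = thermal_voltage(T)
    V = mv_to_v(V_mV)
    zg_f = p.z_g / vt
    po_plus = 1.0 / (1.0 + math.exp(-zg_f * (V - mv_to_v(p.V50_plus))))
    po_minus = 1.0 - 1.0 / (1.0 + math.exp(-zg_f * (V - mv_to_v(p.V50_minus))))
    u = p.z * V / vt
    if abs(u) < 1e-12:
        flux = p.NK_PK * p.z * FARADAY * (p.K_cyt - p.K_out)
    else:
        em = math.exp(-u) if u < 500 else 0.0
        flux = (p.NK_PK * p.z * FARADAY * u * (p.K_cyt - p.K_out * em)
                / -math.expm1(-u))
    return po_plus * po_minus * flux


def chloride_gate_derivative(y: float, x1_eff: float, k_a: float, k_i: float) -> float:
    """dy/dt of the Cl⁻ channel open fraction: k_a·x₁(1−y) − k_i·y, s⁻¹."""
    if not 0.0 <= y <= 1.0:
        raise ArgumentError(f"gate open fraction must lie in [0, 1], got {y}")
    return k_a * x1_eff * (1.0 - y) - k_i * y


def chloride_current(V_mV: float, y: float, G_Cl: float, E_Cl_mV: float) -> float:
    """Ca²⁺-activated Cl⁻ current G_Cl·y·(V − E_Cl), A·m⁻² (inward < 0)."""
    if G_Cl < 0:
        raise ArgumentError("G_Cl must be >= 0")
    return G_Cl * y * mv_to_v(V_mV - E_Cl_mV)


def trp_current(V_mV: float, t: float, p: PassiveParams,
                window: tuple[float, float]) -> float:
    """TRP-like Ca²⁺ current: G_Ca·(V − E_Ca) inside the window, else 0."""
    t_on, t_off = window
    if t_off < t_on:
        raise ArgumentError(f"window must be ordered, got {window}")
    if p.G_Ca == 0.0 or not (t_on <= t < t_off):
        return 0.0
    return p.G_Ca * mv_to_v(V_mV - p.E_Ca)


def total_resting_current(V_mV: float, pump: Optional[PumpParams],
                          passive: PassiveParams) -> float:
    """I_p + I_bkg + I_orc with the Cl⁻ gate closed and no TRP pulse."""
    i = background_current(V_mV, passive.G_bkg, passive.E_bkg)
    i += outward_rectifier_current(V_mV, passive)
    if pump is not None:
        i += pump_current(V_mV, pump)
    return i


def resting_pd(pump_or_params, passive: Optional[PassiveParams] = None, *,
               bracket: tuple[float, float] = (-300.0, -40.0),
               xtol_mV: float = 0.01) -> float:
    """Zero-current membrane PD in mV, by bisection on the given bracket.

    Accepts either ``resting_pd(parameter_set)`` or
    ``resting_pd(pump, passive)`` with pump=None for pump-off columns.
    """
    if passive is None:
        ps = pump_or_params
        pump, passive = ps.pump, ps.passive
    else:
        pump = pump_or_params
    f = lambda v: total_resting_current(v, pump, passive)
    a, b = bracket
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        raise RootFindingError(
            f"no zero-current PD in [{a}, {b}] mV: "
            f"I({a}) = {fa:.4g}, I({b}) = {fb:.4g} A m^-2")
    return float(bisect(f, a, b, xtol=xtol_mV))
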