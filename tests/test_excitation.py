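"""Store-channel kinetics and cytoplasmic Ca²⁺ dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import characean_ap as ca
from characean_ap.excitation import StoreKinetics, StoreState


def test_ip3_bolus_decay():
    # t = 0 identity, zero bolus, and one e-folding-equivalent point
    assert ca.ip3_concentration(2.1, 0.0) == pytest.approx(2.1)
    assert ca.ip3_concentration(0.0, 10.0) == 0.0
    assert ca.ip3_concentration(2.1, 5.0) == pytest.approx(2.1 * math.exp(-1.0))
    with pytest.raises(ca.ArgumentError):
        ca.ip3_concentration(2.1, -1.0)
    with pytest.raises(ca.ArgumentError):
        ca.ip3_concentration(-0.1, 1.0)


def test_ip3_monotone_nonincreasing():
    t = np.linspace(0, 30, 200)
    I = ca.ip3_concentration(1.7, t)
    assert np.all(np.diff(I) <= 0)


def test_state_derivatives_resting_channel():
    kin = StoreKinetics()
    s = StoreState(x1=0.0, x2=1.0, x3=0.0, x4=0.0, x5=0.0)
    assert ca.store_state_derivatives(s, 0.0, kin) == (0.0, 0.0, 0.0, 0.0)


def test_state_derivatives_initial_binding_rate():
    # all channels unbound: only IP3 binding acts, at rate k1*I
    kin = StoreKinetics(k1=12.0)
    s = StoreState(x1=0.0, x2=1.0, x3=0.0, x4=0.0, x5=0.0)
    d2, d3, d4, d5 = ca.store_state_derivatives(s, 2.1, kin)
    assert d2 == pytest.approx(-12.0 * 2.1)
    assert d3 == pytest.approx(+12.0 * 2.1)
    assert d4 == d5 == 0.0


@given(
    x1=st.floats(0.0, 1.0),
    I=st.floats(0.0, 3.0),
    fracs=st.tuples(*[st.floats(0.0, 1.0)] * 4).filter(lambda f: sum(f) > 1e-6),
)
def test_state_derivatives_conserve_mass(x1, I, fracs):
    total = sum(fracs)
    x2, x3, x4, x5 = (f / total for f in fracs)
    kin = StoreKinetics()
    s = StoreState(x1=x1, x2=x2, x3=x3, x4=x4, x5=x5)
    assert abs(sum(ca.store_state_derivatives(s, I, kin))) < 1e-12


def test_calcium_derivative_endpoints(ap_av):
    kin = ap_av.kinetics
    # full store depletion: influx vanishes, saturated pump remains
    d = ca.calcium_derivative(1.0, 0.0, kin)
    p1, p2 = 9.74 / 1.56, 0.0197 / 1.56
    excess = 1.0 - kin.x1_rest
    assert d == pytest.approx(-p1 * excess / (p2 + excess), rel=1e-12)
    assert d == pytest.approx(-6.166, abs=2e-3)
    # zero calcium: pump exactly 0, basal leak remains
    kin0 = kin.replace(gamma0=0.1, nu_r=0.185)
    assert ca.calcium_derivative(0.0, 0.0, kin0) == pytest.approx(1.185 * 0.1)
    for x4 in (0.0, 0.3, 1.0):
        leak = kin.lam * (kin.gamma0 + kin.gamma1 * x4)
        assert ca.calcium_derivative(0.0, x4, kin) == pytest.approx(leak)
    with pytest.raises(ca.ArgumentError):
        ca.calcium_derivative(-0.1, 0.0, kin)


def test_resting_fixed_point_is_stationary(ap_av):
    kin = ap_av.kinetics.replace(I0=0.0, dCa=0.0)
    eq = ca.equilibrium_state(kin)
    t = np.linspace(0.0, 20.0, 501)
    traj = ca.integrate_excitation(kin, t, initial=eq)
    assert abs(traj.x1[-1] - eq.x1) < 1e-6
    assert np.abs(traj.x[:, 1:] - [1, 0, 0, 0]).max() < 1e-8


def test_regenerative_calcium_transient(ap_av):
    """The IP3 bolus plus the Ca2+ pulse ignite a regenerative transient."""
    t = np.arange(0.0, 20.0, 0.01)
    traj = ca.integrate_excitation(ap_av.kinetics, t)
    assert traj.x1.max() > 10.0 * traj.x1[0]
    assert traj.conservation_error().max() < 1e-8
    assert traj.x.min() > -1e-9


def test_oracle_equivalence_short_horizon(ap_av):
    """Adaptive solution matches fixed-step RK4 through the upstroke."""
    from characean_ap.excitation import excitation_rhs

    kin = ap_av.kinetics
    t = np.round(np.arange(0, 501) * 0.01, 10)
    traj = ca.integrate_excitation(kin, t)
    y0 = np.array([kin.x1_rest, 1.0, 0.0, 0.0, 0.0])
    _, y_rk = ca.fixed_step_rk4(excitation_rhs, y0, 0.0, 5.0, 1e-4,
                                t_eval=t, args=(kin,))
    assert np.abs(y_rk[:, 0] - traj.x1).max() < 1e-3


def test_recovery_rate_sets_inactivated_residence(ap_av):
    """k_m3 is the recovery rate from the inactivated state: isolated x5
    mass drains with half-time ln2/k_m3; within the full AP the slow-recovery
    extreme also holds mass far longer than the fitted fast value."""
    halves = []
    for km3 in (0.04, 0.15, 0.312):
        kin = ap_av.kinetics.replace(k_m3=km3, I0=0.0, dCa=0.0)
        t = np.arange(0.0, 40.0, 0.01)
        init = StoreState(x1=kin.x1_rest, x2=0.0, x3=0.0, x4=0.0, x5=1.0)
        traj = ca.integrate_excitation(kin, t, initial=init)
        x5 = traj.fraction(5)
        half = t[np.argmax(x5 <= 0.5)]
        halves.append(half)
        assert half == pytest.approx(math.log(2) / km3, rel=0.05)
    assert halves[0] > halves[1] > halves[2]

    def ap_residence(km3):
        kin = ap_av.kinetics.replace(k_m3=km3)
        t = np.arange(0.0, 40.0, 0.01)
        x5 = ca.integrate_excitation(kin, t).fraction(5)
        ip = int(x5.argmax())
        return t[ip + int(np.argmax(x5[ip:] <= 0.5 * x5[ip]))] - t[ip]

    assert ap_residence(0.04) > ap_residence(0.312)


def test_hill_exponent_controls_repolarization_steepness(ap_av):
    """n = 2 clears the Ca2+ transient faster than n = 1, all else equal."""
    times = {}
    for n in (1, 2):
        kin = ap_av.kinetics.replace(hill_n=n)
        t = np.arange(0.0, 30.0, 0.01)
        x1 = ca.integrate_excitation(kin, t).x1
        ip = int(x1.argmax())
        assert x1[ip] > 10 * x1[0]  # both fire
        decay = np.argmax(x1[ip:] <= 0.1 * x1[ip])
        times[n] = t[ip + decay] - t[ip]
    assert times[2] < times[1]


def test_dCa_window_offsets_consumers(ap_av):
    """Inside its window the pulse drives the state cascade: the conducting
    fraction rises faster than without the pulse."""
    kin = ap_av.kinetics
    t = np.arange(0.0, 0.5, 0.005)
    with_pulse = ca.integrate_excitation(kin, t)
    without = ca.integrate_excitation(kin.replace(dCa=0.0), t)
    i_end = np.searchsorted(t, kin.dCa_window[1])
    assert with_pulse.fraction(4)[i_end] > without.fraction(4)[i_end]


def test_kinetics_validation():
    with pytest.raises(ca.ArgumentError):
        StoreKinetics(hill_n=3)
    with pytest.raises(ca.ArgumentError):
        StoreKinetics(k_m3=-0.1)
    with pytest.raises(ca.ArgumentError):
        StoreKinetics(dCa_window=(0.2, 0.1))
    with pytest.raises(ca.ArgumentError):
        StoreState(x1=0.0, x2=0.7, x3=0.0, x4=0.0, x5=0.0)
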