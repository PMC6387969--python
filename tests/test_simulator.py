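"""Parameter registry, schedules and the coupled AP simulation."""

import numpy as np
import pytest

import characean_ap as ca
from characean_ap.schedules import GclDecay, KappaRamp, Schedule


class TestRegistry:
    def test_average_fit_column_values(self, ap_av):
        kin = ap_av.kinetics
        assert kin.p1_prime == 9.74
        assert kin.p2_prime == 0.0197
        assert kin.k_m3 == 0.312
        assert kin.I0 == 2.1
        assert kin.hill_n == 1
        assert ap_av.pump.kappa_oi == 80.0
        assert ap_av.pump.kio0 == 6500.0
        assert ap_av.passive.G_Cl_max == 4.0
        assert ap_av.passive.k_a == 4.6
        assert ap_av.V0 == -234.0

    def test_blank_cells_inherit_leftward(self, ap_av, chara):
        # unprinted cells carry the reference values unchanged
        for ps in (chara, ap_av):
            assert ps.kinetics.nu_r == 0.185
            assert ps.kinetics.gamma1 == 20.5
            assert ps.kinetics.C0 == 1.56
            assert ps.pump.koi0 == 0.1
            assert ps.passive.NK_PK == 6.5e-7
            assert ps.passive.K_out == 0.1
        assert chara.kinetics.hill_n == 2
        assert ap_av.kinetics.k_m1 == 8.0  # blank, inherited from reference
        assert ap_av.passive.G_bkg == 0.5

    def test_no_pump_column(self):
        ps = ca.load_parameter_set(2, "Cell 3 50 mM NaCl overnight")
        assert ps.pump is None
        assert ps.kinetics.p2_prime == 0.33
        assert ps.kinetics.I0 == 0.15
        assert ps.V0 == -68.0

    def test_strong_saline_pump_column(self):
        ps = ca.load_parameter_set(3, "100 mM NaCl 30 min")
        assert ps.pump.kappa_oi == 950.0
        assert ps.pump.kio0 == 9500.0
        assert ps.passive.G_Cl_max == 80.0

    def test_conductance_decay_column(self):
        ps = ca.load_parameter_set(2, "50 mM NaCl 60 min")
        d = ps.schedule.gcl_decay
        assert d is not None and (d.G_start, d.G_end) == (20.0, 4.1)

    def test_unknown_column_lists_available(self):
        with pytest.raises(ca.UnknownColumnError, match="Cell 1 APW"):
            ca.load_parameter_set(2, "no such column")
        with pytest.raises(ca.UnknownColumnError):
            ca.load_parameter_set(7, "AP_av Chara APW")

    def test_all_columns_load_and_serialize(self):
        for table in (2, 3, 4):
            for col in ca.available_columns(table):
                ps = ca.load_parameter_set(table, col)
                again = ca.ParameterSet.from_dict(ps.to_dict())
                assert again == ps

    def test_derived_ramp_targets_post_excitation_pd(self):
        # the ramp end value is calibrated so the post-AP zero-current PD
        # equals the printed post-excitation resting PD
        ps = ca.load_parameter_set(2, "Cell 1 APW")
        ramp = ps.schedule.kappa_ramp
        assert ramp is not None and ramp.start_value == 80.0
        pd_end = ca.resting_pd(ps.pump.replace(kappa_oi=ramp.end_value),
                               ps.passive)
        assert pd_end == pytest.approx(ps.post_pd, abs=0.05)


class TestSchedules:
    def test_no_schedule_returns_constants(self):
        kappa, gcl = ca.evaluate_schedule(Schedule(), 3.0, 80.0, 4.0)
        assert (kappa, gcl) == (80.0, 4.0)

    def test_kappa_ramp_linear_interpolation(self):
        s = Schedule(kappa_ramp=KappaRamp(1.0, 10.0, 80.0, 40.0))
        assert ca.evaluate_schedule(s, 0.5, 80.0, 4.0)[0] == 80.0
        assert ca.evaluate_schedule(s, 5.5, 80.0, 4.0)[0] == pytest.approx(60.0)
        assert ca.evaluate_schedule(s, 15.0, 80.0, 4.0)[0] == 40.0

    def test_kappa_ramp_recovery_leg(self):
        s = Schedule(kappa_ramp=KappaRamp(1.0, 9.0, 80.0, 40.0,
                                          recovery_value=70.0,
                                          recovery_duration=2.0))
        assert ca.evaluate_schedule(s, 10.0, 80.0, 4.0)[0] == pytest.approx(55.0)
        assert ca.evaluate_schedule(s, 12.0, 80.0, 4.0)[0] == 70.0

    def test_gcl_exponential_decay(self):
        s = Schedule(gcl_decay=GclDecay(20.0, 4.1, duration=5.0, tau=1.0))
        assert ca.evaluate_schedule(s, 0.0, 80.0, 20.0)[1] == pytest.approx(20.0)
        assert ca.evaluate_schedule(s, 1.0, 80.0, 20.0)[1] == pytest.approx(
            4.1 + 15.9 * np.exp(-1.0))
        for t in (5.0, 7.0, 100.0):
            assert ca.evaluate_schedule(s, t, 80.0, 20.0)[1] == 4.1

    def test_ramp_validation(self):
        with pytest.raises(ca.ArgumentError):
            KappaRamp(5.0, 1.0, 80.0, 40.0)


class TestSimulation:
    def test_no_stimulus_no_ap(self, ap_av):
        ps = ca.set_params(ap_av, I0=0.0, dCa=0.0)
        ps = ps.replace(V0=ca.resting_pd(ps), schedule=Schedule())
        res = ca.simulate_ap(ps, t_end=20.0, dt_out=0.01)
        assert np.abs(res.trace.v - res.trace.v[0]).max() < 1.0

    def test_average_ap_peak_in_printed_envelope(self, ap_av_result):
        assert -29.0 <= ap_av_result.peak_mV <= -4.0

    def test_cooperative_pump_repolarizes_faster(self, ap_av, chara,
                                                 ap_av_result):
        """The n = 2 reference fit returns to rest much faster than the
        n = 1 average fit."""
        def recovery_time(res):
            v = res.trace.v
            t = res.trace.t
            rest = v[t <= 0.0].mean()
            ip = int(v.argmax())
            target = rest + 0.1 * (v[ip] - rest)
            below = np.where(v[ip:] <= target)[0]
            return t[ip + below[0]] - t[ip]

        res2 = ca.simulate_ap(chara, t_end=20.0, dt_out=0.01, t_pre=1.0)
        assert recovery_time(res2) < recovery_time(ap_av_result)

    def test_current_bookkeeping_closes_voltage_equation(self, ap_av,
                                                         ap_av_result):
        cur = ap_av_result.currents
        cols = ["I_Cl", "I_p", "I_orc", "I_bkg", "I_TRP"]
        resid = (cur[cols].sum(axis=1)
                 + ap_av.passive.Cm * cur["dVdt"]).abs().max()
        assert resid < 1e-6
        # spot-check each exported column against its pure current function
        st = ap_av_result.states
        for i in (0, 500, 900, 1500):
            v, y, t = ap_av_result.trace.v[i], st.y[i], st.t[i]
            assert cur.I_bkg[i] == pytest.approx(
                ca.background_current(v, ap_av.passive.G_bkg,
                                      ap_av.passive.E_bkg), abs=1e-12)
            assert cur.I_orc[i] == pytest.approx(
                ca.outward_rectifier_current(v, ap_av.passive), abs=1e-12)
            g_cl = ap_av.passive.G_Cl_max
            assert cur.I_Cl[i] == pytest.approx(
                ca.chloride_current(v, min(max(y, 0.0), 1.0), g_cl,
                                    ap_av.passive.E_Cl), abs=1e-12)

    def test_excitability_threshold(self, ap_av, ap_av_result):
        """1% of the IP3 bolus is subthreshold; the full bolus fires."""
        rest = ap_av_result.trace.v[ap_av_result.trace.t <= 0.0].mean()
        assert ap_av_result.peak_mV > rest + 100.0
        small = ca.set_params(ap_av, I0=ap_av.kinetics.I0 * 0.01)
        res = ca.simulate_ap(small, t_end=20.0, dt_out=0.01)
        assert res.peak_mV < ca.resting_pd(ap_av) + 10.0

    def test_pump_inhibition_ramp_lowers_post_ap_pd(self):
        """With the fitted ramp the membrane rests less negative after the
        AP; without it the pre-AP level is recovered."""
        with_ramp = ca.load_parameter_set(2, "Cell 1 APW")
        res = ca.simulate_ap(with_ramp, t_end=30.0, dt_out=0.01)
        assert res.trace.v[-1] > with_ramp.V0 + 5.0
        no_ramp = ca.load_parameter_set(2, "Cell 1 APW", derive_ramp=False)
        res0 = ca.simulate_ap(no_ramp, t_end=30.0, dt_out=0.01)
        assert abs(res0.trace.v[-1] - no_ramp.V0) < 2.0

    def test_grid_and_tolerance_robustness(self, ap_av, ap_av_result):
        fine = ca.simulate_ap(ap_av, t_end=20.0, dt_out=0.005, t_pre=1.0,
                              rtol=1e-9, atol=1e-11)
        assert abs(fine.peak_mV - ap_av_result.peak_mV) < 0.5

    def test_invalid_arguments(self, ap_av):
        with pytest.raises(ca.ArgumentError):
            ca.simulate_ap(ap_av, t_end=-1.0)
        with pytest.raises(ca.ArgumentError):
            ca.simulate_ap(ap_av, t_end=10.0, dt_out=0.0)


class TestParameterAccess:
    def test_set_get_roundtrip(self, ap_av):
        ps = ca.set_param(ap_av, "p1_prime", 7.0)
        assert ca.get_param(ps, "p1_prime") == 7.0
        assert ap_av.kinetics.p1_prime == 9.74  # original untouched

    def test_kappa_update_keeps_ramp_anchored(self, ap_av):
        ps = ca.set_param(ap_av, "kappa_oi", 100.0)
        assert ps.schedule.kappa_ramp.start_value == 100.0

    def test_pump_param_on_pumpless_column_rejected(self):
        ps = ca.load_parameter_set(2, "Cell 3 50 mM NaCl overnight")
        with pytest.raises(ca.ArgumentError, match="no pump"):
            ca.set_param(ps, "kappa_oi", 10.0)

    def test_unknown_name_rejected(self, ap_av):
        with pytest.raises(ca.ArgumentError, match="unknown parameter"):
            ca.get_param(ap_av, "bogus")
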