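"""Trace arithmetic: features, ensemble averaging, tonoplast subtraction."""

import math

import numpy as np
import pytest

import characean_ap as ca


def _flat(v0, n=501, dt=0.01):
    t = dt * np.arange(n)
    return ca.Trace(t, np.full(n, float(v0)))


class TestFeatures:
    def test_constant_trace_has_undefined_transients(self):
        f = ca.ap_features(_flat(-100.0), (0.0, 1.0), (4.0, 5.0))
        assert f.peak == f.rest_pre == f.rest_post == -100.0
        assert math.isnan(f.duration)
        assert math.isnan(f.half_width)

    def test_triangle_half_width(self, triangle_trace):
        f = ca.ap_features(triangle_trace, (5.0, 6.0), (5.0, 6.0))
        assert f.peak == pytest.approx(100.0)
        assert f.t_peak == pytest.approx(2.0)
        assert f.half_width == pytest.approx(2.0, abs=0.02)

    def test_simulated_average_ap_rest_level(self, ap_av_result):
        f = ca.ap_features(ap_av_result.trace, (-1.0, 0.0), (18.0, 20.0))
        assert f.rest_pre == pytest.approx(-234.0, abs=10.0)
        assert -29.0 <= f.peak <= -4.0

    def test_shift_invariance(self, triangle_trace):
        f0 = ca.ap_features(triangle_trace, (5.0, 6.0), (5.0, 6.0))
        shifted = ca.Trace(triangle_trace.t + 3.0, triangle_trace.v)
        f1 = ca.ap_features(shifted, (8.0, 9.0), (8.0, 9.0))
        assert f1.half_width == pytest.approx(f0.half_width, abs=1e-12)
        assert f1.t_peak == pytest.approx(f0.t_peak + 3.0)

    def test_resampling_invariance(self, triangle_trace):
        f0 = ca.ap_features(triangle_trace, (5.0, 6.0), (5.0, 6.0))
        t2 = np.arange(0.0, 6.0 + 1e-12, 0.005)
        v2 = np.interp(t2, triangle_trace.t, triangle_trace.v)
        f2 = ca.ap_features(ca.Trace(t2, v2), (5.0, 6.0), (5.0, 6.0))
        assert f2.half_width == pytest.approx(f0.half_width, abs=0.01)
        assert f2.duration == pytest.approx(f0.duration, abs=0.01)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ca.ArgumentError):
            ca.ap_features(_flat(0.0), (100.0, 101.0), (0.0, 1.0))


class TestAveraging:
    def test_identical_traces_zero_sd(self, triangle_trace):
        e = ca.average_traces([triangle_trace] * 4)
        assert np.allclose(e.mean, triangle_trace.v)
        assert np.allclose(e.sd, 0.0)
        assert e.n == 4

    def test_symmetric_offsets_give_pointwise_sd(self):
        base = _flat(-150.0)
        up = ca.offset_trace(base, +10.0)
        down = ca.offset_trace(base, -10.0)
        e = ca.average_traces([up, down])
        assert np.allclose(e.mean, -150.0)
        assert np.allclose(e.sd, 10.0)  # population SD of {+10, -10}

    def test_mean_peak_bounded_by_member_peaks(self):
        # six synthetic APs with peaks spread over the measured envelope:
        # the ensemble-mean peak stays inside the envelope
        rng = np.random.default_rng(11)
        t = 0.01 * np.arange(301)
        peaks = rng.uniform(-29.0, -4.0, 6)
        traces = [ca.Trace(t, -120.0 + (120.0 + pk)
                           * np.exp(-((t - 1.5) ** 2)))
                  for pk in peaks]
        e = ca.average_traces(traces)
        assert peaks.min() <= e.mean.max() <= peaks.max()
        assert -29.0 <= e.mean.max() <= -4.0

    def test_peak_alignment_registers_maxima(self):
        t = 0.01 * np.arange(1001)
        mk = lambda t0: ca.Trace(t, -np.abs(t - t0) * 10.0)
        e = ca.average_traces([mk(3.0), mk(5.0), mk(7.0)], align="peak")
        assert e.t[np.argmax(e.mean)] == pytest.approx(0.0, abs=0.011)
        assert np.allclose(e.sd, 0.0, atol=1e-9)  # perfectly registered

    def test_empty_list_rejected(self):
        with pytest.raises(ca.ArgumentError):
            ca.average_traces([])


class TestTonoplastSubtraction:
    def test_self_subtraction_zero_mean_quadrature_sd(self):
        t = 0.01 * np.arange(301)
        e = ca.EnsembleTrace(t, np.sin(t) * 30 - 100, np.full(301, 2.0), 6)
        d = ca.subtract_tonoplast(e, e)
        assert np.allclose(d.mean, 0.0)
        assert np.allclose(d.sd, 2.0 * math.sqrt(2))

    def test_3_4_5_quadrature(self):
        t = 0.01 * np.arange(101)
        both = ca.EnsembleTrace(t, np.full(101, -150.0), np.full(101, 3.0), 7)
        pm = ca.EnsembleTrace(t, np.full(101, -164.0), np.full(101, 4.0), 6)
        d = ca.subtract_tonoplast(both, pm)
        assert np.allclose(d.sd, 5.0)
        # constant +14 mV offset: the tonoplast rests at +14 mV
        assert np.allclose(d.mean, 14.0)
        assert d.n == 6

    def test_shorter_record_extended_with_undefined_sd(self):
        t_long = 0.01 * np.arange(201)
        t_short = 0.01 * np.arange(101)
        both = ca.EnsembleTrace(t_long, np.full(201, -150.0),
                                np.full(201, 1.0), 7)
        pm = ca.EnsembleTrace(t_short, np.full(101, -205.0),
                              np.full(101, 1.0), 6)
        d = ca.subtract_tonoplast(both, pm)
        assert len(d.t) == 201
        assert np.allclose(d.mean, 55.0)
        assert np.all(np.isfinite(d.sd[:101]))
        assert np.all(np.isnan(d.sd[101:]))

    def test_incompatible_grids_rejected(self):
        a = ca.EnsembleTrace(0.01 * np.arange(10), np.zeros(10), np.zeros(10), 2)
        b = ca.EnsembleTrace(0.02 * np.arange(10), np.zeros(10), np.zeros(10), 2)
        with pytest.raises(ca.ArgumentError):
            ca.subtract_tonoplast(a, b)


class TestOffsetAndLinearity:
    def test_offset_identity_and_additivity(self, triangle_trace):
        same = ca.offset_trace(triangle_trace, 0.0)
        assert np.array_equal(same.v, triangle_trace.v)
        twice = ca.offset_trace(ca.offset_trace(triangle_trace, 55.0), 55.0)
        assert np.allclose(twice.v, triangle_trace.v + 110.0)

    def test_vacuolar_record_to_tonoplast_scale(self):
        tr = _flat(-41.0)
        assert ca.offset_trace(tr, +55.0).v[0] == pytest.approx(14.0)

    def test_average_and_subtract_commute(self):
        """Linearity: mean(both) - mean(pm) == mean(both_i - pm_i)."""
        rng = np.random.default_rng(5)
        t = 0.01 * np.arange(401)
        boths, pms, diffs = [], [], []
        for _ in range(5):
            vb = -150 + rng.normal(0, 3, 401)
            vp = -200 + rng.normal(0, 3, 401)
            boths.append(ca.Trace(t, vb))
            pms.append(ca.Trace(t, vp))
            diffs.append(ca.Trace(t, vb - vp))
        route1 = ca.subtract_tonoplast(ca.average_traces(boths),
                                       ca.average_traces(pms))
        route2 = ca.average_traces(diffs)
        assert np.abs(route1.mean - route2.mean).max() < 1e-9
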