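"""Patch-clamp feature extraction: passive fits, spike threshold and shape,
afterhyperpolarizations, firing rates, sag/rebound/notch detection."""

import math

import numpy as np
import pytest

from tspn import protocols
from tspn.errors import DetectionError, NotExcitableError, ParameterError
from tspn.features import (ap_metrics, calculated_rheobase, detect_notch,
                           detect_rebound, detect_sag, detect_spikes,
                           detect_threshold, fahp_metrics, firing_rates,
                           fit_passive, ljp_correct,
                           measured_rheobase_from_steps)

from conftest import run_step, synthetic_trace


def _rc_response(delta_v, tau, v_hold, dt=1.0, dur=2000.0):
    t = np.arange(int(dur / dt)) * dt
    return delta_v * np.exp(-t / tau) + (v_hold - delta_v)


class TestPassiveFit:
    def test_exact_recovery_from_generated_trace(self):
        v = _rc_response(delta_v=10.0, tau=100.0, v_hold=-70.0)
        tr = synthetic_trace(v, dt=1.0, step_pa=-10.0)
        fit = fit_passive(tr)
        assert fit.tau_m == pytest.approx(100.0, rel=0.01)
        assert fit.r_in == pytest.approx(1000.0, rel=0.01)
        assert fit.c_m == pytest.approx(100.0, rel=0.01)

    def test_linearity_in_injected_current(self):
        small = fit_passive(synthetic_trace(
            _rc_response(10.0, 100.0, -70.0), dt=1.0, step_pa=-10.0))
        large = fit_passive(synthetic_trace(
            _rc_response(20.0, 100.0, -70.0), dt=1.0, step_pa=-20.0))
        assert large.delta_v == pytest.approx(2 * small.delta_v, rel=1e-6)
        assert large.r_in == pytest.approx(small.r_in, rel=1e-6)

    def test_noise_robust_median_recovery(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(200):
            v = _rc_response(10.0, 100.0, -70.0) \
                + 0.5 * rng.standard_normal(2000)
            fit = fit_passive(synthetic_trace(v, dt=1.0, step_pa=-10.0))
            errs.append(max(abs(fit.tau_m - 100.0) / 100.0,
                            abs(fit.r_in - 1000.0) / 1000.0))
        assert np.median(errs) < 0.03

    def test_zero_current_rejected(self):
        tr = synthetic_trace(_rc_response(10.0, 100.0, -70.0), step_pa=0.0)
        with pytest.raises(ParameterError):
            fit_passive(tr)

    def test_unit_consistency(self):
        fit = fit_passive(synthetic_trace(
            _rc_response(5.0, 60.0, -70.0), dt=1.0, step_pa=-5.0))
        assert fit.c_m == pytest.approx(fit.tau_m / (fit.r_in / 1000.0),
                                        rel=1e-12)


class TestThresholdDetection:
    def test_known_inflection_point(self):
        # slow 1 mV/ms ramp that breaks into a 20 mV/ms upstroke at -45 mV
        dt = 0.1
        ramp = np.arange(-60.0, -45.0, 1.0 * dt)
        stroke = np.arange(-45.0, 20.0, 20.0 * dt)
        down = np.arange(20.0, -60.0, -20.0 * dt)
        v = np.concatenate([np.full(200, -60.0), ramp, stroke, down])
        tr = synthetic_trace(v, dt=dt)
        peak = int(np.argmax(v))
        assert detect_threshold(tr, peak) == pytest.approx(-45.0, abs=1.0)

    def test_criterion_insensitivity_on_model_spikes(self, standard_cell,
                                                     standard_bias):
        # model spikes have a gradual foot, so doubling the dV/dt criterion
        # shifts the detected threshold by a few mV at most
        tr = run_step(standard_cell, standard_bias, 90.0)
        peak = detect_spikes(tr.v, tr.dt)[0]
        th5 = detect_threshold(tr, peak, criterion=5.0)
        th10 = detect_threshold(tr, peak, criterion=10.0)
        assert abs(th5 - th10) < 3.5

    def test_flat_trace_raises(self):
        tr = synthetic_trace(np.full(5000, -60.0))
        with pytest.raises(DetectionError):
            detect_threshold(tr, 2500)


class TestRheobaseEstimates:
    def test_calculated_rheobase_arithmetic(self):
        assert calculated_rheobase(-45.0, -70.0, 1000.0) == pytest.approx(25.0)
        assert calculated_rheobase(-70.0, -70.0, 500.0) == 0.0

    def test_adjacent_step_interpolation_rule(self):
        # 30 pA silent, 40 pA fires several -> estimate 35 pA
        assert measured_rheobase_from_steps(
            [20, 30, 40], [0, 0, 5]) == pytest.approx(35.0)

    def test_single_spike_step_taken_directly(self):
        assert measured_rheobase_from_steps(
            [20, 30], [0, 1]) == pytest.approx(30.0)

    def test_all_subthreshold_raises(self):
        with pytest.raises(NotExcitableError):
            measured_rheobase_from_steps([10, 20, 30], [0, 0, 0])


class TestAPMetrics:
    def _triangle_spike(self, dt=0.1):
        # slow approach to -45 mV then a 50 mV/ms triangular spike to +10
        ramp = np.arange(-60.0, -45.0, 0.1 * dt)
        up = np.arange(-45.0, 10.0, 5.0)
        down = np.arange(10.0, -60.0, -5.0)
        v = np.concatenate([np.full(500, -60.0), ramp, up, down,
                            np.full(500, -60.0)])
        return synthetic_trace(v, dt=dt)

    def test_constructed_amplitude_and_width(self):
        tr = self._triangle_spike()
        peak = int(np.argmax(tr.v))
        m = ap_metrics(tr, peak)
        assert m.amplitude == pytest.approx(10.0 - m.v_threshold, abs=1e-9)
        assert m.v_threshold == pytest.approx(-45.0, abs=1.5)
        half = m.v_threshold + m.amplitude / 2.0
        expected_width = 2 * (10.0 - half) / 50.0  # 50 mV/ms flanks
        assert m.half_width == pytest.approx(expected_width, rel=0.1)


class TestAHP:
    def _single_spike_with_undershoot(self, tau=115.0, amp=15.0, dt=0.1):
        n_pre = 2000
        spike = np.concatenate([np.arange(-50.0, 20.0, 5.0),
                                np.arange(20.0, -65.0, -5.0)])
        t = np.arange(int(30000)) * dt
        under = -50.0 - amp * np.exp(-t / tau)
        v = np.concatenate([np.full(n_pre, -50.0), spike, under])
        return synthetic_trace(v, dt=dt)

    def test_half_decay_of_exponential_undershoot(self):
        tr = self._single_spike_with_undershoot()
        m = fahp_metrics(tr)
        assert m is not None
        assert m.amplitude == pytest.approx(15.0, abs=0.3)
        assert m.half_decay == pytest.approx(115.0 * math.log(2), rel=0.05)
        assert m.duration is not None
        assert m.half_decay < m.duration

    def test_absent_for_multi_spike_trace(self):
        base = self._single_spike_with_undershoot()
        v = base.v.copy()
        v[25000:25010] = 20.0  # second spike
        assert fahp_metrics(synthetic_trace(v)) is None


class TestFiringRates:
    def test_uniform_train_has_no_adaptation(self):
        times = np.arange(100.0, 3000.0, 100.0)
        r = firing_rates(times, (0.0, 3000.0))
        assert np.allclose(r.ifr, 10.0)
        assert r.sra_ratio == pytest.approx(1.0)

    def test_constructed_adaptation_ratio(self):
        # ISIs 50,100,150,200,200,200 ms late in a 3 s step
        times = 1000.0 + np.cumsum([0.0, 50, 100, 150, 200, 200, 200])
        r = firing_rates(times, (0.0, 3000.0))
        assert r.maximal_rate == pytest.approx(20.0)
        assert r.sustained_rate == pytest.approx(5.0)
        assert r.sra_ratio == pytest.approx(4.0)

    def test_sustained_undefined_when_intervals_fall_early(self):
        times = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        r = firing_rates(times, (0.0, 3000.0))
        assert r.sustained_rate is None
        assert r.maximal_rate == pytest.approx(10.0)


class TestSubthresholdSignatures:
    def test_pure_rc_response_has_no_sag(self):
        t = np.arange(30000) * 0.1
        v = np.concatenate([np.full(2000, -70.0),
                            -70.0 - 20.0 * (1 - np.exp(-t / 100.0))])
        tr = synthetic_trace(v, step_window=(2000, v.size))
        present, amp = detect_sag(tr)
        assert not present

    def test_depolarizing_step_rejected_by_sag_detector(self):
        v = np.concatenate([np.full(2000, -70.0), np.full(10000, -60.0)])
        with pytest.raises(DetectionError):
            detect_sag(synthetic_trace(v, step_window=(2000, v.size)))

    def test_rebound_spike_detection(self):
        v = np.full(20000, -70.0)
        v[5000:15000] = -100.0
        tr = synthetic_trace(v.copy(), step_window=(5000, 15000))
        assert not detect_rebound(tr)
        v[16000:16010] = 20.0  # spike 100 ms after offset
        assert detect_rebound(synthetic_trace(v, step_window=(5000, 15000)))

    def test_notch_as_dip_below_charging_exponential(self):
        t = np.arange(20000) * 0.1
        charge = -70.0 + 20.0 * (1 - np.exp(-t / 100.0))
        dip = -2.5 * np.exp(-0.5 * ((t - 150.0) / 30.0) ** 2)
        clean = np.concatenate([np.full(1000, -70.0), charge])
        notched = np.concatenate([np.full(1000, -70.0), charge + dip])
        assert not detect_notch(synthetic_trace(
            clean, step_window=(1000, clean.size)))
        assert detect_notch(synthetic_trace(
            notched, step_window=(1000, notched.size)))


class TestUsahp:
    def _family(self, baselines):
        from tspn.features import detect_usahp
        traces = []
        for b in baselines:
            v = np.concatenate([np.full(2000, b), np.full(5000, b + 20.0)])
            traces.append(synthetic_trace(v, step_window=(2000, 7000)))
        return traces

    def test_progressive_hyperpolarization_below_ek(self):
        from tspn.features import detect_usahp
        assert detect_usahp(self._family([-70.0, -78.0, -85.0, -92.0]))

    def test_stable_baseline_is_negative(self):
        from tspn.features import detect_usahp
        assert not detect_usahp(self._family([-70.0, -70.2, -70.1, -70.0]))

    def test_hyperpolarization_above_ek_is_negative(self):
        from tspn.features import detect_usahp
        assert not detect_usahp(self._family([-70.0, -74.0, -78.0, -82.0]))


class TestLjp:
    def test_absolute_voltages_shifted(self):
        assert ljp_correct(30.0) == pytest.approx(20.0)
        assert ljp_correct(-60.0) == pytest.approx(-70.0)

    def test_amplitudes_invariant(self):
        peak, thr = 30.0, -45.0
        assert (ljp_correct(peak) - ljp_correct(thr)) == pytest.approx(
            peak - thr)

    def test_array_input(self):
        np.testing.assert_allclose(ljp_correct(np.array([0.0, -50.0])),
                                   [-10.0, -60.0])
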