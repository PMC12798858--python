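"""Feature extraction: phase plots, threshold detection at the 10 mV/ms
criterion, AP waveform features against geometric oracles, Rin/tau."""

import math

import numpy as np
import pytest

from fsneuron.cell import VoltageTrace
from fsneuron.features import (
    ap_features,
    detect_aps,
    latency_and_count,
    measure_rin,
    measure_tau,
    phase_plot,
)
from fsneuron.synthetic import SyntheticCellSpec, synth_ap_trace, synth_passive_trace


def _trace(v, dt=0.01):
    return VoltageTrace(dt=dt, t0=0.0, vm=np.asarray(v, float))


class TestPhasePlot:
    def test_linear_ramp_constant_derivative(self):
        t = np.arange(0.0, 10.0, 0.01)
        v, dvdt = phase_plot(_trace(-70.0 + 2.0 * t))
        assert np.allclose(dvdt, 2.0, atol=1e-9)

    def test_sinusoid_max_derivative_is_omega(self):
        dt = 0.001
        t = np.arange(0.0, 20.0, dt)
        omega = 3.0
        _, dvdt = phase_plot(_trace(np.sin(omega * t), dt=dt))
        assert dvdt.max() == pytest.approx(omega, rel=1e-4)

    def test_constant_trace_zero(self):
        _, dvdt = phase_plot(_trace(np.full(100, -70.0)))
        assert np.all(dvdt == 0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            phase_plot(_trace([-70.0, -70.0]))


class TestDetectAPs:
    def test_flat_trace_empty(self):
        assert detect_aps(_trace(np.full(1000, -70.0))) == []

    def test_subthreshold_fast_event_not_counted(self):
        """A fast rise that never reaches the validation level is not an AP."""
        t = np.arange(0.0, 50.0, 0.01)
        v = -70.0 + 20.0 / (1.0 + np.exp(-(t - 25.0) / 0.2))   # tops at -50 mV
        assert detect_aps(_trace(v)) == []

    def test_synthetic_template_threshold_recovered(self):
        spec = SyntheticCellSpec(true_threshold=-41.0, true_peak=12.0)
        tr, ann = synth_ap_trace(spec, spike_times=(30.0,), dt=0.02)
        aps = detect_aps(tr)
        assert len(aps) == 1
        truth = ann["spikes"][0]["threshold"]
        dv_per_sample = 10.0 * tr.dt   # one inter-sample voltage increment
        assert abs(aps[0].threshold - truth) <= dv_per_sample
        assert truth == pytest.approx(-41.0, abs=1e-6)

    def test_epsp_rise_above_criterion_not_taken_as_onset(self):
        """dV/dt > 10 during a fast EPSP must not shadow the later AP onset."""
        dt = 0.01
        t = np.arange(0.0, 60.0, dt)
        epsp = 15.0 * (np.exp(-np.maximum(t - 20.0, 0) / 3.0)
                       - np.exp(-np.maximum(t - 20.0, 0) / 0.3)) * (t >= 20.0)
        spike = 90.0 / (1.0 + np.exp(-(t - 27.0) / 0.15))
        v = -70.0 + epsp + spike
        aps = detect_aps(_trace(v, dt=dt))
        assert len(aps) == 1
        assert aps[0].threshold_time > 25.0   # on the spike, not the EPSP rise


class TestAPFeatures:
    @staticmethod
    def _triangle(peak=10.0, thr=-40.0, trough=-60.0, dt=0.01):
        """Piecewise-linear spike: 1 ms rise, 1 ms fall, AHP, recovery."""
        up = np.linspace(-40.0, peak, int(1.0 / dt), endpoint=False)
        down = np.linspace(peak, trough, int(1.4 / dt), endpoint=False)
        rec = np.linspace(trough, -50.0, int(4.0 / dt), endpoint=False)
        pre = np.full(int(5.0 / dt), -40.0)
        pre[: len(pre) // 2] = -55.0   # keep baseline below threshold early
        v = np.concatenate([np.full(300, -55.0), np.linspace(-55, thr, 200),
                            up, down, rec, np.full(500, -50.0)])
        return _trace(v, dt=dt)

    def test_triangular_half_width_geometry(self):
        tr = self._triangle()
        aps = detect_aps(tr)
        assert len(aps) == 1
        f = ap_features(tr, aps[0])
        # half level -15 mV: rising edge covers 50/50 of its 1 ms, falling
        # edge 25/70 of its 1.4 ms -> 0.5 + 0.5 = 1.0 ms
        assert f.half_width == pytest.approx(1.0, abs=0.03)
        assert f.peak == pytest.approx(10.0, abs=0.05)
        assert f.ahp_amplitude == pytest.approx(-60.0 - f.threshold, abs=0.3)

    def test_no_ahp_below_threshold_marked_missing(self):
        dt = 0.01
        up = np.linspace(-40.0, 10.0, int(1.0 / dt), endpoint=False)
        down = np.linspace(10.0, -35.0, int(1.0 / dt), endpoint=False)  # stays above thr
        v = np.concatenate([np.full(500, -55.0), np.linspace(-55, -40, 200),
                            up, down, np.full(500, -35.0)])
        tr = _trace(v, dt=dt)
        aps = detect_aps(tr)
        f = ap_features(tr, aps[0])
        assert f.ahp_amplitude is None

    def test_max_rise_and_fall_signs(self):
        tr = self._triangle()
        f = ap_features(tr, detect_aps(tr)[0])
        assert f.max_rise > 0 > f.max_fall
        assert f.max_rise == pytest.approx(50.0, rel=0.05)    # 50 mV / 1 ms
        assert f.max_fall == pytest.approx(-50.0, rel=0.05)   # 70 mV / 1.4 ms


class TestLatencyAndCount:
    def test_synthetic_train(self):
        spec = SyntheticCellSpec()
        tr, ann = synth_ap_trace(spec, spike_times=(30.0, 42.0, 55.0, 68.0, 81.0),
                                 dt=0.02)
        lat, count = latency_and_count(tr, step_onset=10.0)
        assert count == 5
        truth = ann["spikes"][0]["threshold_time"] - 10.0
        assert lat == pytest.approx(truth, abs=0.05)

    def test_empty_trace(self):
        lat, count = latency_and_count(_trace(np.full(1000, -70.0)), 10.0)
        assert lat is None and count == 0

    def test_two_spikes_at_known_times(self):
        spec = SyntheticCellSpec()
        tr, ann = synth_ap_trace(spec, spike_times=(30.0, 40.0), dt=0.02)
        lat, count = latency_and_count(tr, step_onset=20.0)
        assert count == 2
        assert lat == pytest.approx(ann["spikes"][0]["threshold_time"] - 20.0,
                                    abs=0.05)


class TestPassiveFeatures:
    def test_rin_single_sweep_division(self):
        tr = synth_passive_trace(188.0, 6.0, step_pA=50.0)
        assert measure_rin([tr], [50.0], 20.0, 250.0) == pytest.approx(188.0, rel=0.01)

    def test_rin_mean_of_equal_ratio_sweeps(self):
        t1 = synth_passive_trace(150.0, 6.0, step_pA=40.0)
        t2 = synth_passive_trace(150.0, 6.0, step_pA=80.0)
        both = measure_rin([t1, t2], [40.0, 80.0], 20.0, 250.0)
        assert both == pytest.approx(measure_rin([t1], [40.0], 20.0, 250.0), rel=1e-6)

    def test_spiking_sweep_excluded_with_warning(self, caplog):
        spec = SyntheticCellSpec()
        spiky, _ = synth_ap_trace(spec, spike_times=(30.0,), dt=0.02, duration=300.0)
        spiky.i_stim = np.full(len(spiky), 50.0)
        clean = synth_passive_trace(150.0, 6.0, step_pA=40.0)
        with caplog.at_level("WARNING"):
            rin = measure_rin([spiky, clean], [50.0, 40.0], 20.0, 250.0)
        assert "excluded" in caplog.text
        assert rin == pytest.approx(150.0, rel=0.01)

    def test_all_sweeps_spiking_is_error(self):
        spec = SyntheticCellSpec()
        spiky, _ = synth_ap_trace(spec, spike_times=(30.0,), dt=0.02, duration=300.0)
        with pytest.raises(ValueError, match="no subthreshold sweep"):
            measure_rin([spiky], [50.0], 20.0, 250.0)

    def test_tau_exact_exponential(self):
        tr = synth_passive_trace(187.9, 6.65, step_pA=53.0)
        assert measure_tau(tr, 20.0) == pytest.approx(6.65, rel=0.01)

    def test_tau_with_noise(self):
        tr = synth_passive_trace(187.9, 6.65, step_pA=53.0, noise_sd=0.2, seed=7)
        assert measure_tau(tr, 20.0) == pytest.approx(6.65, rel=0.05)


class TestSamplingRateStability:
    def test_threshold_and_half_width_stable_under_resampling(self):
        spec = SyntheticCellSpec()
        vals = {}
        for dt in (0.02, 0.01):
            tr, _ = synth_ap_trace(spec, spike_times=(30.0,), dt=dt)
            aps = detect_aps(tr)
            f = ap_features(tr, aps[0])
            vals[dt] = (f.threshold, f.half_width)
        assert abs(vals[0.02][0] - vals[0.01][0]) < 0.2
        assert abs(vals[0.02][1] - vals[0.01][1]) / vals[0.01][1] < 0.02
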