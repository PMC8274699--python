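"""Respiratory gate: differential filtering, breath pulses, window tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinegate import (AmplifierModel, InvalidInputError, PhysioParams,
                      RespGateConfig, ScalerConfig, WaveformTrace,
                      apply_amplifier, detect_breaths, resp_differential,
                      scale_voltage, simulate_respiration, slope_trigger)
from cinegate.resp_gate import _run_gate


def _trace(values, dt=10.0):
    return WaveformTrace(0.0, dt, np.asarray(values, dtype=float))


class TestDifferential:
    def test_constant_trace_gives_zero(self, resp_cfg):
        out = resp_differential(_trace(np.full(50, 2.0)), resp_cfg)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_linear_ramp_gives_constant_step(self, resp_cfg):
        a = 0.003  # V/ms
        t = np.arange(0, 500, 10.0)
        out = resp_differential(_trace(a * t), resp_cfg)
        np.testing.assert_allclose(out.values[1:], a * 10.0, atol=1e-12)

    def test_slow_drift_suppressed(self, resp_cfg):
        """30 s sinusoid of 1 V: per-sample difference bounded by 2*pi*dt/P."""
        t = np.arange(0, 60_000, 10.0)
        out = resp_differential(_trace(np.sin(2 * np.pi * t / 30_000)), resp_cfg)
        bound = 2 * np.pi * 10.0 / 30_000
        assert np.max(np.abs(out.values)) <= bound + 1e-12

    def test_too_short_trace_rejected(self, resp_cfg):
        with pytest.raises(InvalidInputError):
            resp_differential(WaveformTrace(0.0, 10.0, np.array([1.0])), resp_cfg)


class TestBreathDetection:
    def test_termination_level_is_20pct_of_excursion(self):
        """Triangular pulse crossing at 1.0 V, peak 3.0 V -> ends below 1.4 V."""
        up = np.linspace(0, 3.0, 16)      # slow rise: crossing lands on 1.0
        down = np.linspace(3.0, 0, 16)[1:]
        sig = np.concatenate([np.zeros(5), up, down, np.zeros(5)])
        cfg = RespGateConfig(threshold=1.0, no_acquire_extension=0.0)
        # feed the toy signal directly through the interval engine
        res = _run_gate(_trace(np.concatenate([[0], np.cumsum(sig)])), cfg)
        (s, e), = res.threshold_ttl.intervals
        d = res.filtered_trace
        onset_v = d.values[d.index_at(s)]
        end_v = d.values[d.index_at(e)]
        level = onset_v + 0.2 * (3.0 - onset_v)
        assert onset_v == pytest.approx(1.0)
        assert end_v < level <= 1.4 + 1e-9

    def test_no_crossing_means_single_acquire_window(self, resp_cfg):
        res = detect_breaths(_trace(np.zeros(100)), resp_cfg)
        assert res.n_breaths == 0
        assert res.acquire_ttl.intervals == [(0.0, 990.0)]
        assert res.no_acquire_ttl.intervals == []

    def test_counts_match_ground_truth_on_synthetic_respiration(self, resp_cfg):
        """Drift-free synthetic breaths: 100% sensitivity, no false alarms."""
        p = PhysioParams(baseline_drift_amplitude=0.0)
        raw, truth = simulate_respiration(p, 60_000.0, seed=21)
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        res = detect_breaths(scaled, resp_cfg)
        assert res.n_breaths == truth.breath_onset_times.size
        assert res.n_forced_terminations == 0

    def test_detection_survives_baseline_drift(self, resp_cfg):
        """The differential removes the slow drift the threshold would not."""
        p = PhysioParams()  # default 0.5 V drift over 30 s
        raw, truth = simulate_respiration(p, 60_000.0, seed=22)
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        res = detect_breaths(scaled, resp_cfg)
        assert res.n_breaths == truth.breath_onset_times.size

    def test_acquire_and_no_acquire_tile_timeline(self, clean_respiration, resp_cfg):
        raw, _ = clean_respiration
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        res = detect_breaths(scaled, resp_cfg)
        ivs = sorted(res.acquire_ttl.intervals + res.no_acquire_ttl.intervals)
        assert ivs[0][0] == res.acquire_ttl.t0
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == pytest.approx(s2)
        assert ivs[-1][1] == pytest.approx(res.acquire_ttl.t1)

    def test_threshold_pulses_inside_no_acquire(self, clean_respiration, resp_cfg):
        raw, _ = clean_respiration
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        res = detect_breaths(scaled, resp_cfg)
        for s, e in res.threshold_ttl.intervals:
            assert res.no_acquire_ttl.level_at(s)
            assert res.no_acquire_ttl.level_at(max(s, e - 1e-6))

    @pytest.mark.parametrize("ext", [0.0, 50.0, 150.0, 400.0])
    def test_extension_monotonically_grows_no_acquire(self, clean_respiration, ext):
        raw, _ = clean_respiration
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        base = detect_breaths(scaled, RespGateConfig(no_acquire_extension=ext))
        more = detect_breaths(scaled, RespGateConfig(no_acquire_extension=ext + 25))
        assert more.no_acquire_ttl.total_high_time() >= base.no_acquire_ttl.total_high_time()

    def test_acquire_max_duration_truncates_but_still_tiles(self, clean_respiration):
        raw, _ = clean_respiration
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        cfg = RespGateConfig(acquire_max_duration=300.0)
        res = detect_breaths(scaled, cfg)
        for s, e in res.acquire_ttl.intervals:
            assert e - s <= 300.0 + 1e-9
        total = res.acquire_ttl.total_high_time() + res.no_acquire_ttl.total_high_time()
        assert total == pytest.approx(res.acquire_ttl.t1 - res.acquire_ttl.t0)

    def test_stuck_pulse_force_terminated(self):
        """A step that never returns through its termination level times out."""
        sig = np.concatenate([np.zeros(5), np.full(100, 1.0)])
        cfg = RespGateConfig(threshold=0.5, pulse_timeout=200.0)
        res = detect_breaths(_trace(np.cumsum(sig)), cfg)
        assert res.n_forced_terminations >= 1


class TestSlopeMode:
    def _pulse(self, rise_ms, amp=2.0, dt=10.0):
        """Triangular pulse with controllable leading-edge slope."""
        up = np.linspace(0, amp, int(rise_ms / dt) + 1)
        down = np.linspace(amp, 0, int(rise_ms / dt) + 1)[1:]
        v = np.concatenate([np.zeros(20), up, down, np.zeros(20)])
        return _trace(v, dt)

    def test_slow_edge_invisible_to_slope_mode(self):
        tr = self._pulse(rise_ms=400.0)   # slope 0.005 V/ms
        slope_cfg = RespGateConfig(mode="slope", threshold=0.02)
        assert slope_trigger(tr, slope_cfg).n_breaths == 0
        diff_cfg = RespGateConfig(threshold=0.03)  # 0.05 V per 10 ms sample
        assert detect_breaths(tr, diff_cfg).n_breaths == 1

    def test_slope_onset_not_later_than_amplitude_onset(self):
        """On a symmetric triangle, slope arming fires at the first rising
        sample while an amplitude threshold waits for the level crossing."""
        tr = self._pulse(rise_ms=100.0, amp=2.0)
        slope_cfg = RespGateConfig(mode="slope", threshold=0.015)
        s_res = slope_trigger(tr, slope_cfg)
        # amplitude-style detection oracle: first sample >= 1.0 V
        t_amp = tr.times[np.argmax(tr.values >= 1.0)]
        assert s_res.threshold_ttl.starts[0] <= t_amp

    def test_one_detection_per_breath_on_clean_train(self, clean_respiration):
        raw, truth = clean_respiration
        amp = apply_amplifier(raw, AmplifierModel.resp_default())
        scaled, _ = scale_voltage(amp, ScalerConfig())
        cfg = RespGateConfig(mode="slope", threshold=0.005)
        res = slope_trigger(scaled, cfg)
        assert res.n_breaths == truth.breath_onset_times.size
        assert np.all(np.diff(res.threshold_ttl.starts) > 0)
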