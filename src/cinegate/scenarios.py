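"""Reference QC scenarios: canned simulations quantifying gating performance.

These are the desk-scale checks a site would run before trusting the gating
chain on a scanner: trigger-jitter statistics of the constant-TR gate
evaluation loop, end-to-end R-wave synchrony under gradient noise, simulator
period statistics, and reconstruction of the per-slice scan time of the
high-throughput CINE protocol.  Each function is deterministic given its
seed and returns plain dictionaries of numbers.
"""

from __future__ import annotations

import numpy as np

from .conditioning import AmplifierModel, ScalerConfig, apply_amplifier, scale_voltage
from .ecg_gate import ECGGateConfig, detect_r_waves, detection_latency
from .physio import (PhysioParams, add_gradient_noise, r_wave_peak_to_peak,
                     simulate_cardiac)
from .scan_control import ScanParams, run_scan, scan_time_summary, trigger_jitter_stats
from .ttl import TTLSignal

__all__ = ["trigger_jitter_benchmark", "rwave_synchrony_benchmark",
           "cardiac_period_statistics", "gated_scan_time_benchmark"]


def trigger_jitter_benchmark(n_triggers: int = 10_000, seed: int = 0,
                             tr: float = 4.0, rr: float = 134.0) -> dict:
    """First-frame delay distribution for triggers with uniform TR phase.

    Because the gate line is sampled once per TR, a trigger landing anywhere
    within a TR period starts its first CINE frame at the next tick: the
    delay is uniform over one TR with mean 0.5*TR.
    """
    rng = np.random.default_rng(seed)
    onsets = np.arange(1, n_triggers + 1) * rr + rng.uniform(0.0, tr, size=n_triggers)
    ttl = TTLSignal.from_intervals([(t, t + 16.0) for t in onsets],
                                   0.0, onsets[-1] + 100.0)
    sched = run_scan(ttl, ScanParams(tr=tr, n_phase_encodes=n_triggers))
    js = trigger_jitter_stats(sched, ttl, tr=tr)
    counts, _ = js.histogram(bins=10)
    return {
        "n_triggers": int(js.delays.size),
        "mean_delay_ms": js.mean,
        "mean_delay_in_tr": js.mean_in_tr,
        "histogram_counts": counts.tolist(),
    }


def rwave_synchrony_benchmark(n_beats: int = 200, seed: int = 0,
                              amplifier_delay: float = 3.5,
                              noise_fraction: float = 0.2) -> dict:
    """End-to-end cardiac-gate latency under worst-case gradient noise.

    Simulates the full ECG chain — jittered beats, amplifier delay and
    broadening, voltage scaling, per-TR gradient bursts at the stated
    fraction of the R-wave peak-to-peak — then runs the two-rate detector
    and measures TTL-onset latency against the true (pre-amplifier) R-peaks.
    """
    ss = np.random.SeedSequence(seed)
    seed_sim, seed_noise = (int(s) % (2**31) for s in ss.generate_state(2))
    params = PhysioParams(gradient_noise_fraction=noise_fraction)
    duration = params.cardiac_period_mean * (n_beats + 2)
    trace, truth = simulate_cardiac(params, duration, seed_sim)
    amp = AmplifierModel(propagation_delay=amplifier_delay, smoothing_width=4.0)
    conditioned = apply_amplifier(trace, amp)
    scaled, _ = scale_voltage(conditioned, ScalerConfig())
    if noise_fraction > 0:
        ref = r_wave_peak_to_peak(scaled, truth)
        scaled = add_gradient_noise(scaled, 4.0, 1.0, noise_fraction, ref, seed_noise)
    result = detect_r_waves(scaled, ECGGateConfig())
    lat = detection_latency(result, truth)
    return {
        "n_beats": int(truth.r_peak_times.size),
        "n_detected": int(result.detected_peaks.size),
        "n_missed": lat.n_missed,
        "n_false": lat.n_false,
        "max_latency_ms": lat.max,
        "mean_latency_ms": lat.mean,
    }


def cardiac_period_statistics(n_beats: int = 1000, seed: int = 0) -> dict:
    """Sample statistics of the simulator's R-R intervals at default dials."""
    params = PhysioParams()
    duration = params.cardiac_period_mean * (n_beats + 4)
    _, truth = simulate_cardiac(params, duration, seed)
    rr = np.diff(truth.r_peak_times)[:n_beats]
    return {
        "n_intervals": int(rr.size),
        "mean_rr_ms": float(rr.mean()),
        "min_rr_ms": float(rr.min()),
        "max_rr_ms": float(rr.max()),
    }


def gated_scan_time_benchmark(seeds, rr_mean: float = 134.0, rr_span: float = 10.0,
                              resp_mean: float = 1500.0, resp_span: float = 100.0,
                              no_acquire_duration: float = 150.0,
                              params: ScanParams | None = None) -> dict:
    """Per-slice scan time of the gated CINE protocol, averaged over seeds.

    Event-level reconstruction: cardiac TTL pulses at jittered R-times, a
    respiratory no-acquire window of the stated duration per breath, Boolean
    AND combination, then the full tick state machine with breath declaration
    and re-acquisition.
    """
    params = params or ScanParams()
    durations, breaths, reacq = [], [], []
    for seed in np.atleast_1d(seeds):
        rng = np.random.default_rng(int(seed))
        horizon = 90_000.0
        r = np.cumsum(rng.uniform(rr_mean - rr_span, rr_mean + rr_span,
                                  size=int(horizon / (rr_mean - rr_span)) + 2))
        r = r[r < horizon - 300.0]
        ecg = TTLSignal.from_intervals([(t, t + 16.0) for t in r], 0.0, horizon)
        b = np.cumsum(rng.uniform(resp_mean - resp_span, resp_mean + resp_span,
                                  size=int(horizon / (resp_mean - resp_span)) + 2))
        b = b[b < horizon - 300.0]
        acq = TTLSignal.from_intervals(
            [(t, t + no_acquire_duration) for t in b], 0.0, horizon).complement()
        cr = ecg.logical_and(acq)
        sched = run_scan(cr, params)
        s = scan_time_summary(sched)
        durations.append(s["total_duration_ms"])
        breaths.append(s["breaths_declared"])
        reacq.append(s["reacquired_blocks"])
    return {
        "n_seeds": int(np.atleast_1d(seeds).size),
        "mean_scan_time_s": float(np.mean(durations) / 1000.0),
        "std_scan_time_s": float(np.std(durations) / 1000.0),
        "mean_breaths_declared": float(np.mean(breaths)),
        "mean_reacquired_blocks": float(np.mean(reacq)),
    }
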