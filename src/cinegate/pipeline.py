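"""End-to-end composition: simulate → condition → gate → combine → scan →
magnetization, with artifact export.

Stage order mirrors the physical signal pathway: the physiological voltages
pass through the channel amplifiers, then the ±10 V → 0–5 V scaling board;
gradient-switching noise is injected on the scaled ECG (it is picked up in
the detection circuit and survives the front end); the gating unit then
digitizes the conditioned traces and produces the respiratory, cardiac and
combined control lines; the scanner state machine consumes the combined line.
Every artifact carries the seed and a configuration hash, and runs are
bit-deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import conditioning, ecg_gate, magnetization, physio, resp_gate, scan_control
from .config import RunConfig
from .errors import CinegateError
from .trace import WaveformTrace
from .ttl import TTLSignal

__all__ = ["PipelineResult", "run_pipeline", "export_trace_bundle"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    cardiac_truth: physio.EventGroundTruth
    resp_truth: physio.EventGroundTruth
    raw_ecg: WaveformTrace
    raw_resp: WaveformTrace
    scaled_ecg: WaveformTrace
    scaled_resp: WaveformTrace
    resp_result: resp_gate.RespGateResult
    ecg_result: ecg_gate.ECGGateResult
    cr_ttl: TTLSignal
    schedule: scan_control.AcquisitionSchedule | None
    record: magnetization.MagnetizationRecord | None
    summary: dict


def _derive_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent child seeds (< 2**31) for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig, output_dir=None, run_scan: bool = True,
                 run_magnetization: bool = True) -> PipelineResult:
    """Execute the full pipeline; optionally write artifacts to ``output_dir``."""
    stage = "setup"
    try:
        seeds = _derive_seeds(config.seed)
        p = config.physio

        stage = "physio_sim"
        raw_ecg, cardiac_truth = physio.simulate_cardiac(p, config.duration, seeds[0])
        raw_resp, resp_truth = physio.simulate_respiration(p, config.duration, seeds[1])

        stage = "conditioning"
        amp_ecg = conditioning.apply_amplifier(raw_ecg, config.ecg_amplifier)
        amp_resp = conditioning.apply_amplifier(raw_resp, config.resp_amplifier)
        scaled_ecg, n_clip_e = conditioning.scale_voltage(amp_ecg, config.scaler)
        scaled_resp, n_clip_r = conditioning.scale_voltage(amp_resp, config.scaler)

        stage = "gradient_noise"
        if config.noise.enabled and p.gradient_noise_fraction > 0:
            ref = physio.r_wave_peak_to_peak(scaled_ecg, cardiac_truth)
            scaled_ecg = physio.add_gradient_noise(
                scaled_ecg, config.noise.burst_period, config.noise.burst_width,
                p.gradient_noise_fraction, ref, seeds[2])

        stage = "resp_gate"
        rg = (resp_gate.detect_breaths if config.resp_gate.mode == "differential"
              else resp_gate.slope_trigger)(scaled_resp, config.resp_gate)

        stage = "ecg_gate"
        eg = ecg_gate.detect_r_waves(scaled_ecg, config.ecg_gate)

        stage = "combine"
        cr = ecg_gate.combine_gates(eg.ecg_ttl, rg.acquire_ttl)

        schedule = record = None
        if run_scan:
            stage = f"scan_control[{config.scan.mode}]"
            if config.scan.mode == "tSSM":
                schedule = scan_control.run_scan(cr, config.scan)
            elif config.scan.mode == "cCRT":
                schedule = scan_control.run_scan_ccrt(eg.ecg_ttl, rg.acquire_ttl,
                                                      config.scan)
            else:
                schedule = scan_control.run_scan_dg(eg.ecg_ttl, config.scan,
                                                    rg.acquire_ttl)
            if run_magnetization:
                stage = "magnetization"
                record = magnetization.evolve(schedule, config.tissue, config.sequence)

        stage = "summary"
        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "true_beats": int(cardiac_truth.r_peak_times.size),
            "detected_beats": int(eg.detected_peaks.size),
            "true_breaths": int(resp_truth.breath_onset_times.size),
            "detected_breaths": rg.n_breaths,
            "clipped_samples_ecg": n_clip_e,
            "clipped_samples_resp": n_clip_r,
        }
        if schedule is not None:
            summary.update(scan_control.scan_time_summary(schedule))
        result = PipelineResult(
            config=config, cardiac_truth=cardiac_truth, resp_truth=resp_truth,
            raw_ecg=raw_ecg, raw_resp=raw_resp, scaled_ecg=scaled_ecg,
            scaled_resp=scaled_resp, resp_result=rg, ecg_result=eg, cr_ttl=cr,
            schedule=schedule, record=record, summary=summary,
        )
    except CinegateError as err:
        log.error("pipeline failed in stage %s: %s", stage, err)
        raise CinegateError(f"stage {stage}: {err}") from err

    if output_dir is not None:
        _export(result, Path(output_dir))
    return result


def _export(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": res.config.seed, "config_hash": res.config.config_hash()}
    res.raw_ecg.to_csv(out / "raw_ecg.csv")
    res.raw_resp.to_csv(out / "raw_resp.csv")
    res.scaled_ecg.to_csv(out / "scaled_ecg.csv")
    res.scaled_resp.to_csv(out / "scaled_resp.csv")
    for name, ttl in [("resp_threshold_ttl", res.resp_result.threshold_ttl),
                      ("resp_no_acquire_ttl", res.resp_result.no_acquire_ttl),
                      ("resp_acquire_ttl", res.resp_result.acquire_ttl),
                      ("ecg_ttl", res.ecg_result.ecg_ttl),
                      ("cr_ttl", res.cr_ttl)]:
        obj = ttl.to_json()
        obj.update(meta)
        with open(out / f"{name}.json", "w") as fh:
            json.dump(obj, fh, indent=1)
    truth = res.cardiac_truth.to_json()
    truth.update(res.resp_truth.to_json())
    truth.update(meta)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
    if res.schedule is not None:
        res.schedule.to_jsonl(out / "schedule.jsonl")
    if res.record is not None:
        res.record.to_csv(out / "magnetization.csv")
    summary = dict(res.summary)
    summary.update(meta)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


def export_trace_bundle(res: PipelineResult, path, sample_interval: float = 1.0) -> None:
    """Write the nine-channel signal-pathway bundle as one CSV.

    Columns follow the recording-system channel layout: raw and scaled
    respiration, the respiration threshold and gate lines, raw and scaled
    ECG, the ECG difference, the cardiac gate and the combined
    cardio-respiratory gate, all resampled onto a common grid.
    """
    t0 = res.scaled_ecg.start_time
    t1 = min(res.scaled_ecg.end_time, res.scaled_resp.end_time)
    n = int(np.floor((t1 - t0) / sample_interval)) + 1
    t = t0 + np.arange(n) * sample_interval

    def sample(trace: WaveformTrace):
        idx = np.clip(np.round((t - trace.start_time) / trace.sample_interval)
                      .astype(int), 0, trace.n_samples - 1)
        return trace.values[idx]

    def render(ttl: TTLSignal):
        return np.where(ttl.level_at(t), 5.0, 0.0)

    pd.DataFrame({
        "time_ms": t,
        "raw_resp": sample(res.raw_resp),
        "scaled_resp": sample(res.scaled_resp),
        "resp_thresh_ttl": render(res.resp_result.threshold_ttl),
        "resp_gate_ttl": render(res.resp_result.acquire_ttl),
        "raw_ecg": sample(res.raw_ecg),
        "scaled_ecg": sample(res.scaled_ecg),
        "ecg_diff": sample(res.ecg_result.difference_trace),
        "ecg_ttl": render(res.ecg_result.ecg_ttl),
        "cr_ttl": render(res.cr_ttl),
    }).to_csv(path, index=False)
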