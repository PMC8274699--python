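# cinegate

Software re-implementation of an open-hardware **gating control unit (GCU)**
for prospective cardio-respiratory gating in small-animal MRI, together with a
simulator of the prospectively gated, **steady-state-maintained CINE**
acquisition it drives. Gating schemes can be designed, stress-tested and
compared entirely at the desk — no scanner, no hardware, no animals.

## Who this is for

Preclinical MRI physicists and instrumentation developers who need to:

* prototype respiration/ECG gating logic (thresholds, trailing-edge rules,
  TTL polarities, refractory periods) against realistic, corrupted signals;
* quantify trigger latency and jitter budgets before committing to hardware;
* compare conventional cardio-respiratory triggering (**cCRT**), double
  gating (**DG**) and true steady-state maintenance (**tSSM**) in terms of
  signal stability and scan time.

## What is implemented

**Signal chain** (all times ms, amplitudes volts):

* `physio` — seeded synthetic ECG and respiration generators with ground
  truth. Periods jitter uniformly about mean ± span (defaults 134 ± 10 ms
  cardiac, 1000 ± 100 ms respiratory, the mouse regime); per-TR
  gradient-switching noise bursts up to a set fraction of the R-wave
  peak-to-peak voltage.
* `conditioning` — amplifier propagation delay and peak broadening (a ~2.5 ms
  R-wave leaves the ECG amplifier ~7 ms wide and 4 ms late), and the
  ±10 V → 0–5 V voltage-scaling board with gain/offset dials and saturation
  counting.
* `resp_gate` — 10 ms digitization, 2-point differential high-pass,
  threshold binarisation (dTTL_Threshold), trailing-edge termination at
  +20 % of the onset-to-peak excursion, user-dialled extension
  (dTTL_NoAcquire) and the complementary acquire window (dTTL_Acquire);
  plus a slope-trigger mode.
* `ecg_gate` — two-rate R-wave detection: 1 kHz baseline sampling, 2-point
  difference across a 4 ms lag, threshold arming, 10 kHz burst sampling and
  turning-point peak localisation (amplitude- and DC-independent), immediate
  dTTL_ECG generation, refractory re-arming; Boolean AND combination with
  the respiratory acquire window.
* `scan_control` — the pulse-sequence looping structure as a TR-tick state
  machine: gate evaluation once per TR, NE-frame CINE block per trigger,
  breath declaration after >25 idle ticks (100 ms at TR = 4 ms) and
  automatic re-acquisition of the 2 preceding k-space blocks; cCRT and DG
  comparison modes; trigger-jitter statistics.
* `magnetization` — spoiled gradient-echo (FLASH) longitudinal evolution:
  `Mz(t+Δ) = M0 + (Mz − M0)·exp(−Δ/T1)` between pulses, signal
  `Mz·sin α·exp(−TE/T2*)` per pulse, steady state
  `M0(1−E1)/(1−E1 cos α)`, `E1 = exp(−TR/T1)`; short/long-term
  coefficient-of-variation stability metrics.

## Worked example

Run the full chain — simulate 40 s of physiology, condition, gate, scan 128
phase encodes in tSSM mode, evolve magnetization — and write all artifacts:

```bash
cinegate run --seed 3 --out run3
```

prints

```json
{
 "breaths_declared": 34,
 "detected_beats": 298,
 "detected_breaths": 41,
 "kept_blocks": 128,
 "reacquired_blocks": 68,
 "seed": 3,
 "total_duration_ms": 33680.0,
 "true_beats": 298,
 "true_breaths": 41
}
```

Every one of the 298 simulated R-waves produced a gating pulse despite the
gradient noise; all 41 breaths were detected. 34 breaths fell inside the
scan, each discarding and re-queuing the 2 preceding CINE blocks
(68 re-acquisitions), and the 128-line scan completed in 33.7 s. The output
directory holds the traces (CSV), TTL lines (JSON), per-block schedule
(JSON lines) and the magnetization series (CSV), all stamped with the seed
and a configuration hash.

The changeover bookkeeping of a high-throughput session:

```bash
cinegate throughput
# {"mean_changeover_min": 9.2, "mice_per_hour": 6.52, "n_changes": 5,
#  "total_span_min": 50.0}
```

Library use mirrors the CLI: see `cinegate.run_pipeline`, or compose the
stage functions (`simulate_cardiac`, `apply_amplifier`, `detect_r_waves`,
`run_scan`, `evolve`, …) directly.

## Layout

```
src/cinegate/    library (one module per stage, plus config/pipeline/cli)
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
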