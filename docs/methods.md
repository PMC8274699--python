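# Methods

This note records the models behind `cinegate`, the parameter choices that
matter, and what the simulations can and cannot say about real data.

## The problem being modelled

Prospective ECG gating in small-animal MRI must detect the R-wave within a
few milliseconds in the presence of gradient-switching pickup, and must
handle respiration either by suspending imaging (cCRT), by pulsing through
breaths but discarding corrupted data (DG), or — the scheme this package
centres on — by keeping RF and gradients running at one constant TR
throughout (tSSM) while TTL gates toggle only *data acquisition*. tSSM keeps
the spoiled-gradient-echo steady state intact, so frame intensities depend
only on M0, T1, T2\*, flip angle and TR; the price is that breaths can only
be detected after they have begun, which the acquisition absorbs by
re-acquiring the k-space blocks collected just before each detected breath.

## Synthetic physiology

Only the period statistics of the emulated device's built-in simulator are
documented: cardiac 134(±10) ms and respiratory 1000(±100) ms, with "span"
read as the half-width of an independent uniform jitter per interval. The
waveform shapes are this package's own modelling choices:

* **R-wave**: positive Gaussian, FWHM 2.5 ms (the true pre-amplifier width),
  amplitude 1 V, with −15 % side lobes at ±1.5 widths — the minimal shape
  with a sharp rising edge for the difference filter and a well-defined
  turning point. Peak times are snapped to the 10 kHz master grid so trace
  argmax and ground truth coincide exactly.
* **Respiration-coupled ECG baseline**: a sinusoid at the respiratory period
  (default amplitude 0.5 V) rides under the ECG so that the 4 ms difference
  filter has exactly the slow disturbance it exists to remove.
* **Breath**: unipolar raised cosine, width 200 ms, amplitude 6 V (a mouse
  at 40–60 breaths/min spends roughly a fifth of its cycle in motion), on a
  slow sinusoidal drift (default 0.5 V over 30 s) standing in for thermal
  and positional baseline wander.
* **Gradient noise**: bursts every TR (4 ms) of 1 ms width, oscillating at a
  quarter of the sample rate with random per-burst sign and phase, truncated
  to whole cycles so the injected component sums to exactly zero. Amplitude
  is specified as a fraction of the R-wave peak-to-peak voltage; 0.2 is the
  documented worst case. The random phase matters: without it the 1 kHz
  base-rate path would systematically sample the oscillation's zeros.

Everything is simulated at 10 kHz (the device's fastest digitization rate)
and decimated for the slower channels, which reproduces the two-rate
detector's view of the world without resampling artefacts.

## Analogue front end

The documented facts about the amplifiers are: a 4 ms ECG propagation delay,
broadening of a ~2.5 ms R-wave to ~7 ms, a slew-rate limiter, and a >50 ms
respiration low-pass delay. The filter families themselves are proprietary,
so the model is a pure delay plus a normalized moving average — the simplest
linear operator reproducing both documented numbers (ECG defaults: 4 ms
delay, 4 ms window; respiration: 52 ms delay, 30 ms window). The slew-rate
clamp is available but off by default (its parameters are undocumented). The
scaling board maps ±10 V affinely onto 0–5 V; its gain dial multiplies about
the output midrange and out-of-range samples saturate (counted, not
raised as errors — the hardware saturates rather than fails).

## Gating algorithms

**Respiration.** Digitized every 10 ms; all crossings are sample-and-compare
on that grid (no sub-sample interpolation), as in the microprocessor loop.
In differential mode both arming and termination act on the 2-point
differential; the onset voltage is the first sample at/above threshold, and
the pulse ends when the signal falls through
`onset + 0.2·(max − onset)` — the trailing-fraction rule that prevents
artificially long pulses when the baseline is not re-reached between
breaths. Pulses whose trailing edge never crosses the termination level are
force-terminated after 400 ms (2× the default breath width) and logged. The
no-acquire extension defaults to 150 ms — a user dial on the hardware,
chosen here to cover the breath tail remaining after the differential
terminates near the breath peak. The >50 ms respiration amplifier delay is
deliberately *not* compensated: blocks acquired during the undetected breath
onset are recovered by re-acquisition, exactly as in the hardware scheme.
In slope mode the pulse starts when the per-sample slope (V/ms) exceeds the
threshold and terminates on the analogue voltage returning through 20 % of
the detection-to-peak excursion.

**ECG.** The base path evaluates the 4 ms-lag difference at 1 kHz; arming
occurs when it exceeds the threshold (default 0.08 V on the 0–5 V scale:
comfortably above the worst-case noise step of ~0.04 V and below the R-wave
step of ~0.12 V under default dials — the hardware exposes this as a
per-subject dial). The fast path then walks 10 kHz samples; the first
strict decrease marks the turning point and the *predecessor* is the peak
(flat tops resolve to the first plateau sample — deterministic and
hardware-plausible). The TTL rises at the detection instant, one fast
sample after the peak. Sampling reverts to the base rate at the peak (the
alternative — reverting at TTL end — would only lengthen the blind window).
Re-arming is inhibited for a refractory period defaulting to the TTL
duration (16 ms: longer than one TR, shorter than the 80 ms CINE block).
An armed excursion with no turning point within 20 ms disarms and logs
(noise-burst safeguard). Intra-breath R-waves are detected; suppression
happens only in the Boolean AND with the respiratory acquire window.

## Scan control

The scanner clock ticks at TR = 4 ms; the gate level is read once per tick.
This quantization is what produces the first-frame trigger jitter: a trigger
with uniform phase relative to the tick clock starts its block with a delay
uniform over one TR, mean 0.5·TR. Breath declaration is strict: the 26th
consecutive idle tick (>25, i.e. 100 ms) declares, once per idle stretch,
and re-queues the 2 most recently kept blocks at the front of the queue. If
fewer kept blocks exist, only those are re-queued; no declaration can occur
before the first block (there is nothing to invalidate). After the last
pending phase encode, gate evaluation continues until the next trigger
confirms that no breath invalidated the final blocks — without this the
re-acquisition guarantee would not cover breaths arriving immediately after
scan "completion". In tSSM mode every tick is an RF pulse, so the RF
interval multiset is exactly {TR} regardless of gating. cCRT pulses RF only
inside blocks; DG pulses an NE-frame block after *every* beat (truncated
and flagged if R-R < NE·TR, a case the hardware description leaves open)
and keeps data only for triggers inside the acquire window.

## Magnetization

Perfect spoiling is assumed (RF and gradient spoiling are part of the
emulated protocol), so only Mz evolves: exponential recovery between pulses,
`cos α` loss per pulse, echo amplitude `Mz·sin α·exp(−TE/T2*)`. Defaults
TE = 1.89 ms, TR = 4 ms, flip angles 5–30°, and a muscle-like tissue at 7 T
(T1 = 1500 ms, T2\* = 20 ms) — placeholders for the stable-tissue ROI; no
quantitative intensity match to any measured image is claimed or tested,
only the structural claims: recursion ≡ closed form at constant TR,
constancy of tSSM signals, elevation of post-gap first frames, and the
stability ordering cCRT > DG > tSSM in short-term CV at moderate flip
angles. Inflow and ghosting are not modelled.

## Problem sizes and numerical choices

The packaged QC scenarios use 10,000 triggers for jitter statistics, 200
beats for the latency benchmark, 1000 intervals for period statistics, and
20 seeds of the 128-encode scan for the scan-time reconstruction — sizes at
which Monte-Carlo error is well below the tolerances being checked while a
full run stays in the seconds range. The scan-time scenario pins R-R to
134 ± 10 ms, breaths to 1500 ± 100 ms with a 150 ms no-acquire window per
breath, and reconstructs ~23 s per 128-line slice. Seeds derive from a
single master seed via `numpy.random.SeedSequence`; identical configuration
and seed reproduce every artifact byte-for-byte. Interval containers use
half-open `[start, end)` semantics throughout; ties at tick boundaries
resolve in favour of the earlier state transition.

## What passing tests do and do not show

The generators reproduce the *timing* statistics and the gross morphology
the gating logic depends on (sharp R upslope, slow breath pulse, zero-mean
burst noise, baseline wander). They do not reproduce PQRST morphology,
arrhythmias, magnetohydrodynamic artefacts, multipolar respiration signals
or electrode-dependent noise coupling — so passing tests demonstrate the
correctness and latency budget of the *algorithms*, not detection
performance on any particular animal or electrode setup. Image
reconstruction, k-space effects and ghosting are out of scope.
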