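# Methods

This note records the models, parameter choices and numerical
conventions behind each module, what the synthetic data do and do not
emulate, and the known limitations.

## Synthetic overnight recordings (`synth`)

The generator emulates what the implanted device sees across a night in
a small rodent: alternating wake and NREM epochs, with NREM dominated
by slow-wave (SW, 0.5–4 Hz) oscillations whose power is slowly
modulated at an ultradian rate, and an accelerometer that is quiet in
sleep and busy in wake.

**Sleep architecture.** Wake/NREM alternation is a seeded two-state
semi-Markov schedule: NREM bout lengths are exponential with mean
300 s (floored at 30 s), and the wake bout mean is derived from the
target NREM fraction (default 0.75 → 100 s). These bout scales were
chosen so the alternation's own spectral content (~9 cycles/h
timescale) sits above the 1–6 cycles/h band where ultradian cycles are
assessed. Real rodent sleep has heavier-tailed bout distributions and
REM episodes; neither is modeled (REM is an explicit non-goal).

**The SW component.** Within NREM, the SW signal is an
amplitude-modulated sinusoid: carrier frequency follows a reflected
random walk on 10-s control points confined to the central 80% of
0.5–4 Hz, and the instantaneous phase is the cumulative integral of
that frequency track. This makes the phase analytically known per
sample — `true_phase_fn` — which is what lets closed-loop phase
accuracy be scored exactly. The SW envelope is
`A·(0.5 + 0.5·cos(2π·r·t/3600))` for cycle rate `r` in cycles/hour
(full-depth modulation), with 1-s raised-cosine ramps at bout edges;
the phase is reported as undefined (NaN) in wake and inside the ramps.

**Amplitudes** are conventional rodent cortical values, not measured
ones: SW peak 150 μV, NREM broadband floor 15 μV RMS, wake broadband
30 μV RMS. The wake/NREM background has a power-law spectrum with
default slope 0.5 (near-broadband, desynchronized wake EEG); this
keeps SW-band power below a quarter of total power in every 30-s wake
window, so wake epochs are never SW-dominated. All samples fit a
signed 24-bit front end at the default 0.1 μV/LSB gain with two
orders of magnitude of headroom. The generator produces already
high-passed (zero-DC) signals, mirroring the hardware's 0.25 Hz
analog high-pass, so the detector applies no extra detrending.

**Accelerometer.** Three axes at 1 Hz (or 10 Hz): resting jitter of
0.01 g in NREM; in wake, 0.25 g baseline activity plus sparse 0.8 g
movement bursts. No gravity offset, posture or gyroscope modeling.

Passing tests on these data show that the downstream algorithms are
correct *given* their assumptions (near-sinusoidal SW with slowly
varying frequency, stationary noise floors, crisp state labels); they
do not show robustness to real EEG morphology, artifacts, electrode
drift, or REM theta.

## Slow-wave detector (`detector`)

The cascade mirrors the embedded implementation: a 2-s rolling buffer
evaluated every 100 ms, with evaluation times floored to the sample
grid (the device uses a wall-clock timer; 100 ms is 12.5 samples at
125 Hz).

* **Center frequency.** Largest-magnitude FFT bin within 0.5–12 Hz,
  DC excluded, on the fixed 0.5 Hz grid (tails are zero-padded to the
  buffer length so the grid never coarsens — without padding a 2.5 Hz
  rhythm would be unresolvable on a 1-s window). The search band
  includes the 6–12 Hz reference band deliberately: a dominant fast
  rhythm pulls F꜀ out of the SW band and fails the first gate, which
  is the ratio gate's intent.
* **Phase.** Least-squares projection of the analyzed samples onto
  cos/sin at F꜀ with t = 0 at the *last* sample, so the reported phase
  is the phase at the detection instant that stimulation delays count
  forward from. Projection avoids the leakage-induced phase bias of
  reading the FFT coefficient's argument on short windows. On
  noiseless on-grid sinusoids this is exact to well under 0.5°,
  including on the tail path.
* **Band power.** Summed squared FFT magnitudes over bins inside each
  band (inclusive edges). Whether the device sums magnitudes or squared
  magnitudes is not documented; squared magnitude is the default and
  `power_def="magnitude"` is available.
* **Amplitude gate.** Causal Butterworth band-pass (order 4 overall,
  i.e. a 2-section biquad cascade, matching the device's biquad IIR
  filtering; never zero-phase), max |y| taken over the second half of
  the window so the filter's start-up transient cannot trip the gate.
* **Tail path.** If the full-buffer F꜀ exceeds 2 Hz the entire cascade
  — including the amplitude gate — is re-evaluated on the final 1 s,
  and the tail estimate is the one reported.
* **Refractory period.** 4 s after each detection (the trial buffer
  length), during which evaluations are suppressed. Default ratio
  (2.0) and amplitude (80 μV) thresholds are working values for the
  synthetic data; on the device both are user-set per experiment.

The 16-byte wire form is four little-endian 32-bit fields: time (ms,
unsigned), trial number (unsigned), F꜀ and phase (IEEE single). The
`used_tail` flag is local diagnostic state, not transmitted.

## Stimulus scheduling (`stim`)

Phase convention: signal = cos(phase), so the up-going zero crossing —
the stimulation target — is 270°. The scheduler solves for the
smallest delay ≥ the modeled latency satisfying
`φ_detect + 360·F꜀·delay/1000 ≡ φ_target (mod 360)`, then quantizes to
the scheduling resolution (default 1 ms), bumping up one step if
rounding fell below the latency floor; tones are *centered* on the
target phase (onset = center − 25 ms for the 50-ms tone).

Latency defaults are the measured device figures: 20.06 ms full-buffer
runtime, 25.55 ms tail-path runtime (selected per trial by which path
produced the detection), and wireless latency 10.17 ± 1.74 ms modeled
as a Gaussian truncated at zero — the BLE connection-interval
quantization is subsumed into that distribution rather than modeled
discretely. The published "30° lag at 2.5 Hz" corresponds to ~33.3 ms
of total latency while the component sum is 35.72 ms; the discrepancy
(rounding, or a different component set) cannot be resolved from the
published figures, so the total is fully configurable and the delay
law is what the package asserts. Sham trials are an independent
Bernoulli(0.1) draw per detection; they carry the red LED marker and
no tone, and are excluded from (but counted in) phase-accuracy
summaries, which use circular statistics throughout.

## Packet codec (`packets`)

One packet = one 32-bit word: 8-bit type code, 24-bit payload,
big-endian on disk (fixed here; the hardware documentation does not
state endianness). The type-code table is this package's own: EEG
channels 0x01–0x04 (24-bit two's-complement front-end codes),
accelerometer axes 0x10–0x12, vitals voltage (mV) 0x20 and temperature
(centi-°C) 0x21, absolute-time marker (s) 0x30, event marker 0x40.
High-rate samples carry no timestamp; the parser counts at the nominal
rate from the preceding time marker (NaN before the first marker).
Vitals are three single-value packets per minute, time marker first so
the readings that follow it are stamped.

Guards: below 2.4 V the device resets settings to defaults and halts
writes, latching until an explicit reset; a full memory (default
capacity 2 Gbit / 32 bits = 67,108,864 packets) rejects further
writes. Rejections are statuses, not exceptions. Parsing is total on
arbitrary bytes: 0xFFFFFFFF is the erased-NAND sentinel that
terminates a dump, unknown type codes are preserved and counted, a
truncated trailing word is reported, and every input byte is
classified exactly once (tested as an invariant).

## Power budget (`power`)

Power is computed against the 1.8 V regulated main rail (this, and
only this, reproduces every published power figure); lifetime is
capacity/current/24 days on the 240 mAh cell. Displayed values
truncate toward zero — one decimal below 10 days, whole days above —
which matches every published lifetime (4.347→4.3, 3.571→3.5,
20.83→20, 76.92→76) where rounding would not. Power display units
follow each row's printed current unit (μA rows in μW). The Shelf and
Beacon catalog rows quote lifetimes inconsistent with capacity/current
(their currents are evidently peak draws with radio duty cycling
behind the quoted endurance); those lifetimes are carried as quoted
metadata and never recomputed. The battery model is purely coulombic:
no temperature derating or internal-resistance modeling (the catalog's
85 °F operating point is metadata only).

## Sleep-cycle analysis (`sleep_cycle`)

SW power over time: spectrogram with 30-s Hann windows at 50% overlap
(resolving the 0.5 Hz band floor while sampling the envelope every
15 s), PSD averaged across the 0.5–4 Hz bins. Cycle spectrum:
periodogram of the mean-removed series, frequency axis in cycles/hour,
DC excluded. Permutation test: surrogates are seeded whole-series
shuffles; per-bin p = (1 + exceedances) / (1 + n) (add-one estimator,
so the floor with 10,000 surrogates is ~1.0×10⁻⁴, and 1,000
surrogates still resolve α = 0.001).

**Family-wise significance.** The per-bin p-values follow the
described procedure exactly, but an 8-h series has ~960 frequency
bins, so declaring a cycle whenever *any* bin clears a raw α = 0.001
would flag a spurious peak in most featureless recordings (family-wise
error ≈ 0.62). `analyze_sleep_cycle` therefore decides significance
with the standard max-statistic permutation correction computed from
the same surrogate sweep — each bin's observed power against the
surrogate distribution of the maximum across bins — and reports the
most powerful family-wise-significant bin. Per-bin p-values remain
available for calibration work.

**Limitation: autocorrelated series.** Whole-series shuffling tests
exchangeability. A SW-power series with strong autocorrelation from
wake/NREM bout alternation violates that null even with no ultradian
modulation, making the test anti-conservative on such data; block or
phase-randomized surrogates would be the remedy but are out of scope
here. Null-behavior tests therefore use constant-SW recordings
(nrem_fraction = 1, cycle_rate = 0), where exchangeability holds.

## Problem sizes and determinism

Parameter-recovery checks run five cycle rates (1–6 cycles/h) × 10
seeds on 8-h synthetic nights with 1,000 surrogates each; closed-loop
precision uses a 10-min pure 2.5 Hz input (~150 trials); detector
oracle equivalence uses 1,000 random buffers against brute-force DFT
sums and a hand-rolled difference-equation filter. Every stochastic
component takes an explicit seed (numpy `default_rng`); identical
seeds give bit-identical recordings, trials and p-values.
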