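"""Closed-loop phase-locked stimulation on a pure slow wave.

A noiseless 2.5 Hz slow wave is streamed through detection; each
detection schedules a 50-ms tone whose center targets the up-going
zero crossing (270 deg), compensating the algorithm runtime (tail
path: 25.55 ms) and wireless latency (10.17 ms).  Ground truth then
scores where each tone actually landed.
"""

import biologger as bl

recording = bl.sinusoid_recording(freq=2.5, amplitude=150.0, duration=600.0)
latency = bl.LatencyModel(wireless_dist="fixed")  # fixed at the measured means
trials = bl.simulate_closed_loop(
    recording, bl.DetectorConfig(), latency, sham_prob=0.1, seed=42
)
summary = bl.evaluate_phase_accuracy(trials)

lag = bl.latency_phase_lag(2.5, latency.algo_ms_tail + latency.wireless_mean_ms)
print(f"uncompensated lag at 2.5 Hz: {lag:.1f} deg")
print(f"{summary.n_stim} tones + {summary.n_sham} shams")
print(f"mean |phase error| {summary.mean_abs_error_deg:.3f} deg "
      f"(circular SD {summary.circular_sd_deg:.3f} deg)")
# With the latency modeled and subtracted, the residual error is set
# only by the 1-ms scheduling grid — far inside the 1.5 deg budget.
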