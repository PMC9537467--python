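"""Run the on-device detection cascade over a synthetic recording.

The detector re-analyzes a rolling 2-s buffer every 100 ms: FFT center
frequency in 0.5-4 Hz, slow-wave/reference band power ratio, and
band-pass amplitude all have to clear their gates.  Detections should
land in NREM, where the slow waves live.
"""

import numpy as np

import biologger as bl

rec = bl.make_overnight(bl.SynthConfig(duration=1200.0, seed=3))
config = bl.DetectorConfig(ratio_threshold=3.0, amplitude_threshold=100.0)
detections = bl.run_detector(rec.eeg, config)

in_nrem = [
    rec.state_labels[max(0, int(d.time * 125) - 249) : int(d.time * 125) + 1].mean() > 0.5
    for d in detections
]
print(f"{len(detections)} detections in {rec.eeg.duration / 60:.0f} min "
      f"({np.mean(rec.state_labels):.0%} NREM)")
print(f"detections inside NREM: {np.mean(in_nrem):.0%}")
if detections:
    d = detections[0]
    wire = bl.serialize_detection(d)
    print(f"first: t={d.time:.1f}s fc={d.fc} Hz phase={d.phase_at_fc:.1f} deg "
          f"tail={d.used_tail} -> {len(wire)}-byte wire form")
# fc is the dominant slow-wave frequency; phase is referenced to the
# detection instant, ready for latency-compensated stimulation.
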