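"""Real-time slow-wave detection cascade.

Mirrors the embedded closed-loop algorithm: a rolling 2-s buffer of
single-channel EEG is re-analyzed every 100 ms.  Each evaluation

1. takes an FFT of the buffer and finds the center frequency ``fc``
   (largest-magnitude bin in the search band) and the phase at ``fc``,
   referenced to the last buffer sample (the detection instant);
2. gates on ``fc`` falling inside the slow-wave (SW) band 0.5-4 Hz;
3. gates on the SW-band / 6-12 Hz reference-band power ratio;
4. gates on the max amplitude of the causally band-pass-filtered
   (Butterworth) SW signal;
5. if ``fc`` exceeds 2 Hz, reruns the whole cascade on only the final
   1 s of data for better temporal sensitivity, zero-padding the tail
   so the 0.5 Hz frequency grid is preserved, and reports the tail
   estimate.

A successful detection packages (time, trial number, fc, phase) —
exactly 16 bytes on the wire.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .traces import EEGTrace

__all__ = [
    "DetectorConfig",
    "SpectralEstimate",
    "DetectionResult",
    "NoDominantFrequencyError",
    "estimate_spectrum",
    "sw_amplitude",
    "detect",
    "run_detector",
    "serialize_detection",
    "deserialize_detection",
]


class NoDominantFrequencyError(ValueError):
    """Raised when a window carries no signal to take a spectrum of."""


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the detection cascade.

    ``ratio_threshold`` and ``amplitude_threshold`` are user-set on the
    device; the defaults here are working values for the synthetic
    recordings, not device calibrations.  ``power_def`` selects whether
    band "power" means summed squared FFT magnitudes (default) or summed
    magnitudes.
    """

    fs: float = 125.0
    buffer_s: float = 2.0
    step_s: float = 0.1
    sw_band: tuple[float, float] = (0.5, 4.0)
    ref_band: tuple[float, float] = (6.0, 12.0)
    fc_search_band: tuple[float, float] = (0.5, 12.0)
    ratio_threshold: float = 2.0
    amplitude_threshold: float = 80.0
    tail_s: float = 1.0
    fc_rerun_cutoff: float = 2.0
    filter_order: int = 4
    refractory_s: float = 4.0
    power_def: str = "squared_magnitude"

    def __post_init__(self) -> None:
        for name in ("buffer_s", "tail_s"):
            n = getattr(self, name) * self.fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name}·fs must be an integer sample count")
        if max(self.sw_band[0], self.ref_band[0]) <= min(self.sw_band[1], self.ref_band[1]):
            raise ValueError("sw_band and ref_band must not overlap")
        if not self.sw_band[0] <= self.fc_rerun_cutoff <= self.sw_band[1]:
            raise ValueError("fc_rerun_cutoff must lie inside sw_band")
        if self.filter_order % 2 or self.filter_order <= 0:
            raise ValueError("filter_order must be a positive even integer")
        if self.power_def not in ("squared_magnitude", "magnitude"):
            raise ValueError("power_def must be 'squared_magnitude' or 'magnitude'")

    @property
    def buffer_n(self) -> int:
        return int(round(self.buffer_s * self.fs))

    @property
    def tail_n(self) -> int:
        return int(round(self.tail_s * self.fs))

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sw_band" in raw:
            raw["sw_band"] = tuple(raw["sw_band"])
        if "ref_band" in raw:
            raw["ref_band"] = tuple(raw["ref_band"])
        if "fc_search_band" in raw:
            raw["fc_search_band"] = tuple(raw["fc_search_band"])
        return cls(**raw)


@dataclass(frozen=True)
class SpectralEstimate:
    """FFT summary of one analysis window."""

    fc: float
    phase_at_fc: float  # degrees in [0, 360), referenced to the last sample
    sw_power: float
    ref_power: float
    window_len_s: float


@dataclass(frozen=True)
class DetectionResult:
    """The 16-byte detection metadata sent to the base station.

    ``used_tail`` is local diagnostic state (which analysis path
    produced the estimate); it is not part of the wire format.
    """

    time: float  # seconds since session start
    trial_number: int
    fc: float
    phase_at_fc: float
    used_tail: bool = False


def estimate_spectrum(window, fs: float, config: DetectorConfig) -> SpectralEstimate:
    """Center frequency, phase and band powers of one analysis window.

    The window must be a full buffer or a tail; tails are zero-padded to
    the buffer length so the frequency grid spacing stays at
    ``1/buffer_s`` Hz.  ``fc`` is the largest-magnitude bin inside the
    search band (DC excluded).  The phase is a least-squares cosine fit
    at ``fc`` over the *actual* samples, referenced to the last sample —
    the instant the stimulation delay counts forward from.
    """
    x = np.asarray(window, dtype=np.float64)
    nbuf, ntail = config.buffer_n, config.tail_n
    if x.size not in (nbuf, ntail):
        raise ValueError(
            f"window length {x.size} is neither a buffer ({nbuf}) nor a tail ({ntail})"
        )
    if not np.any(x):
        raise NoDominantFrequencyError("all-zero window has no dominant frequency")

    padded = x if x.size == nbuf else np.concatenate([x, np.zeros(nbuf - x.size)])
    spec = np.fft.rfft(padded)
    freqs = np.fft.rfftfreq(nbuf, d=1.0 / fs)
    mags = np.abs(spec)

    lo, hi = config.fc_search_band
    search = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not np.any(search):
        raise NoDominantFrequencyError("empty search band")
    idx = np.flatnonzero(search)
    fc = float(freqs[idx[np.argmax(mags[idx])]])

    # Least-squares projection onto cos/sin at fc, t = 0 at the LAST sample.
    t = (np.arange(x.size) - (x.size - 1)) / fs
    design = np.column_stack(
        [np.cos(2 * np.pi * fc * t), np.sin(2 * np.pi * fc * t)]
    )
    (a, b), *_ = np.linalg.lstsq(design, x, rcond=None)
    phase = float(np.degrees(np.arctan2(-b, a)) % 360.0)

    power = mags**2 if config.power_def == "squared_magnitude" else mags
    sw = (freqs >= config.sw_band[0]) & (freqs <= config.sw_band[1])
    ref = (freqs >= config.ref_band[0]) & (freqs <= config.ref_band[1])
    return SpectralEstimate(
        fc=fc,
        phase_at_fc=phase,
        sw_power=float(np.sum(power[sw])),
        ref_power=float(np.sum(power[ref])),
        window_len_s=x.size / fs,
    )


def _sw_sos(config: DetectorConfig) -> np.ndarray:
    # butter() doubles the order for band-pass designs; the device runs
    # the equivalent biquad cascade causally.
    return sps.butter(
        config.filter_order // 2,
        config.sw_band,
        btype="bandpass",
        fs=config.fs,
        output="sos",
    )


def sw_amplitude(window, config: DetectorConfig) -> float:
    """Max |amplitude| of the causally SW-band-filtered window.

    Evaluated on the second half only, so the Butterworth start-up
    transient does not count toward the gate.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < config.fs * 1.0:
        raise ValueError("window shorter than the 1-s filter warm-up")
    y = sps.sosfilt(_sw_sos(config), x)
    return float(np.max(np.abs(y[x.size // 2 :])))


def _gate(est: SpectralEstimate, amp: float, config: DetectorConfig) -> Optional[str]:
    """Name of the first failing gate, or None if all pass."""
    if not config.sw_band[0] <= est.fc <= config.sw_band[1]:
        return "fc_band"
    ratio = est.sw_power / est.ref_power if est.ref_power > 0 else np.inf
    if ratio < config.ratio_threshold:
        return "power_ratio"
    if amp < config.amplitude_threshold:
        return "amplitude"
    return None


def detect(
    window,
    config: DetectorConfig,
    trial_number: int = 0,
    t: float = 0.0,
    diagnostics: Optional[dict] = None,
) -> Optional[DetectionResult]:
    """Run the full cascade on one 2-s buffer.

    Returns a :class:`DetectionResult` when every gate passes, else
    ``None``.  If the full-buffer ``fc`` exceeds the rerun cutoff the
    cascade is re-evaluated on the final tail second and the tail
    estimate is the one reported (``used_tail`` set).  When a gate
    fails, its name is recorded in ``diagnostics`` if a dict is given.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size != config.buffer_n:
        raise ValueError("detect() expects a full buffer window")

    def fail(reason: str) -> None:
        if diagnostics is not None:
            diagnostics["failed_gate"] = reason

    try:
        est = estimate_spectrum(x, config.fs, config)
    except NoDominantFrequencyError:
        fail("no_dominant_frequency")
        return None
    reason = _gate(est, sw_amplitude(x, config), config)
    if reason is not None:
        fail(reason)
        return None

    used_tail = False
    if est.fc > config.fc_rerun_cutoff:
        tail = x[-config.tail_n :]
        try:
            est = estimate_spectrum(tail, config.fs, config)
        except NoDominantFrequencyError:
            fail("no_dominant_frequency_tail")
            return None
        reason = _gate(est, sw_amplitude(tail, config), config)
        if reason is not None:
            fail(reason + "_tail")
            return None
        used_tail = True

    if diagnostics is not None:
        diagnostics["failed_gate"] = None
    return DetectionResult(
        time=t,
        trial_number=trial_number,
        fc=est.fc,
        phase_at_fc=est.phase_at_fc,
        used_tail=used_tail,
    )


def run_detector(trace: EEGTrace, config: DetectorConfig) -> list[DetectionResult]:
    """Stream a trace through the cascade at the 100-ms cadence.

    Evaluations start once the buffer first fills (t = buffer_s) and
    repeat every ``step_s``, each using the most recent buffer of
    samples; evaluation times are floored to the sample grid (the device
    runs on a wall-clock timer, not a sample counter).  After a
    detection, evaluations are suppressed for ``refractory_s`` (the
    4-s trial buffer) before resuming.
    """
    x = trace.samples
    n = x.size
    nbuf = config.buffer_n
    if n < nbuf:
        raise ValueError("trace shorter than one analysis buffer")
    results: list[DetectionResult] = []
    suppress_until = -np.inf
    k = 0
    while True:
        t_eval = config.buffer_s + k * config.step_s
        end = int(np.floor(t_eval * config.fs))
        if end > n:
            break
        k += 1
        if t_eval < suppress_until:
            continue
        t_det = trace.t0 + (end - 1) / config.fs  # time of the last sample
        res = detect(x[end - nbuf : end], config, trial_number=len(results), t=t_det)
        if res is not None:
            results.append(res)
            suppress_until = t_eval + config.refractory_s
    return results


_WIRE = struct.Struct("<IIff")  # time_ms, trial_number, fc, phase — 16 bytes


def serialize_detection(result: DetectionResult) -> bytes:
    """Pack a detection into its 16-byte wire form.

    Four little-endian 32-bit fields: time in ms (unsigned), trial
    number (unsigned), fc and phase (IEEE single).
    """
    time_ms = int(round(result.time * 1000.0))
    if not 0 <= time_ms < 2**32:
        raise OverflowError("time does not fit an unsigned 32-bit millisecond count")
    if not 0 <= result.trial_number < 2**32:
        raise OverflowError("trial_number does not fit 32 bits")
    return _WIRE.pack(time_ms, result.trial_number, result.fc, result.phase_at_fc)


def deserialize_detection(payload: bytes) -> DetectionResult:
    """Inverse of :func:`serialize_detection` (``used_tail`` not carried)."""
    if len(payload) != _WIRE.size:
        raise ValueError(f"detection payload must be {_WIRE.size} bytes")
    time_ms, trial, fc, phase = _WIRE.unpack(payload)
    return DetectionResult(
        time=time_ms / 1000.0, trial_number=trial, fc=fc, phase_at_fc=phase
    )
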