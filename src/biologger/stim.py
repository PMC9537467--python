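"""Phase-locked stimulus scheduling and closed-loop simulation.

A detection hands over (fc, phase at the detection instant).  Between
that instant and any audible tone lie fixed costs: algorithm runtime on
the device (20.06 ms full-buffer, 25.55 ms when the tail rerun is
taken) and BLE wireless latency (10.17 ± 1.74 ms measured).  At 2.5 Hz
those latencies alone correspond to tens of degrees of phase, so the
scheduler solves for the smallest delay, no shorter than the modeled
latency, that lands the tone *center* on the target phase of the
ongoing rhythm — by convention signal = cos(phase), so the up-going
zero crossing is 270°.

Against a synthetic recording the achieved phase is read from the
ground-truth phase function at the tone center, giving an exact score
of the closed loop's phase precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .detector import DetectionResult, DetectorConfig, run_detector
from .synth import SynthRecording

__all__ = [
    "LatencyModel",
    "StimulusPlan",
    "ClosedLoopTrial",
    "PhaseAccuracySummary",
    "NoStimTrialsError",
    "UP_GOING_PHASE_DEG",
    "phase_delay",
    "latency_phase_lag",
    "simulate_closed_loop",
    "evaluate_phase_accuracy",
]

#: Ascending zero crossing in the cos(phase) convention.
UP_GOING_PHASE_DEG: float = 270.0


class NoStimTrialsError(ValueError):
    """Raised when a summary is requested but every trial was a sham."""


@dataclass(frozen=True)
class LatencyModel:
    """Fixed-cost latencies between detection and audible stimulus.

    Defaults are the measured device figures (ms).  ``wireless_dist``
    selects a fixed draw at the mean or a Gaussian truncated at zero;
    the BLE connection-interval quantization is subsumed into that
    distribution.
    """

    algo_ms_full: float = 20.06
    algo_ms_tail: float = 25.55
    wireless_mean_ms: float = 10.17
    wireless_sd_ms: float = 1.74
    wireless_dist: str = "gaussian"  # or "fixed"
    scheduling_resolution_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.algo_ms_full, self.algo_ms_tail, self.wireless_mean_ms) < 0:
            raise ValueError("latencies must be non-negative")
        if self.algo_ms_tail < self.algo_ms_full:
            raise ValueError("tail-path runtime cannot be below the full-buffer runtime")
        if self.wireless_dist not in ("fixed", "gaussian"):
            raise ValueError("wireless_dist must be 'fixed' or 'gaussian'")
        if self.scheduling_resolution_ms <= 0:
            raise ValueError("scheduling_resolution_ms must be positive")

    def draw_wireless(self, rng: np.random.Generator) -> float:
        if self.wireless_dist == "fixed" or self.wireless_sd_ms == 0:
            return self.wireless_mean_ms
        while True:  # Gaussian truncated at 0
            v = rng.normal(self.wireless_mean_ms, self.wireless_sd_ms)
            if v >= 0:
                return v

    def algo_ms(self, used_tail: bool) -> float:
        return self.algo_ms_tail if used_tail else self.algo_ms_full

    @classmethod
    def from_yaml(cls, path) -> "LatencyModel":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class StimulusPlan:
    """One scheduled tone (or sham): delay from detection to tone center."""

    delay_ms: float
    tone_ms: float = 50.0
    target_phase: float = UP_GOING_PHASE_DEG
    sham: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.target_phase < 360:
            raise ValueError("target_phase must lie in [0, 360)")

    @property
    def onset_ms(self) -> float:
        """Tone onset relative to detection (center − half the tone)."""
        return self.delay_ms - self.tone_ms / 2.0


@dataclass(frozen=True)
class ClosedLoopTrial:
    """One stimulation or sham event with its peri-detection data.

    ``achieved_phase`` is read from synthetic ground truth at the tone
    center (NaN for shams, which deliver no tone).  ``marker`` mirrors
    the device LED: green = stimulus, red = sham.
    """

    detection: DetectionResult
    plan: StimulusPlan
    peri_data: np.ndarray  # 2 s pre + 2 s post detection
    achieved_phase: float
    marker: str

    def __post_init__(self) -> None:
        if self.marker not in ("green", "red"):
            raise ValueError("marker must be 'green' (stim) or 'red' (sham)")
        if self.plan.sham != (self.marker == "red"):
            raise ValueError("marker inconsistent with sham flag")


def latency_phase_lag(fc: float, latency_ms: float) -> float:
    """Phase accumulated during a latency: ``360·fc·latency`` degrees.

    At 2.5 Hz, 33.33 ms of latency costs 30° of phase — the lag the
    scheduler exists to compensate.
    """
    return 360.0 * fc * latency_ms / 1000.0


def phase_delay(
    fc: float,
    phase_at_detect: float,
    total_latency_ms: float,
    target_phase: float = UP_GOING_PHASE_DEG,
    scheduling_resolution_ms: float = 1.0,
) -> float:
    """Smallest delay ≥ the modeled latency that lands on the target phase.

    Solves ``phase_at_detect + 360·fc·delay/1000 ≡ target (mod 360)``
    for the smallest admissible delay, then quantizes to the scheduler's
    resolution — rounding to the nearest step, bumped up a step if
    rounding fell below the latency floor.
    """
    if fc <= 0:
        raise ValueError("fc must be positive")
    if total_latency_ms < 0:
        raise ValueError("total_latency_ms must be non-negative")
    period_ms = 1000.0 / fc
    base = ((target_phase - phase_at_detect) % 360.0) / 360.0 * period_ms
    k = max(0.0, np.ceil((total_latency_ms - base) / period_ms - 1e-12))
    delay = base + k * period_ms
    res = scheduling_resolution_ms
    delay = res * round(delay / res)
    while delay < total_latency_ms - 1e-9:
        delay += res
    return float(delay)


def simulate_closed_loop(
    recording: SynthRecording,
    det_config: DetectorConfig,
    latency: LatencyModel,
    sham_prob: float = 0.1,
    seed: int = 0,
    target_phase: float = UP_GOING_PHASE_DEG,
    tone_ms: float = 50.0,
) -> list[ClosedLoopTrial]:
    """Run the full detect → delay → tone pipeline on a recording.

    Every detection spawns one trial.  Per trial, the wireless latency
    is drawn from the latency model, the algorithm latency is picked by
    which analysis path produced the detection, and an independent
    Bernoulli(``sham_prob``) draw decides sham status.  Detections
    within 2 s of the trace end are dropped (incomplete peri buffer)
    with a warning.  Deterministic per seed.
    """
    if recording.eeg.duration < 4.0:
        raise ValueError("recording must be at least 4 s long")
    if not 0 <= sham_prob <= 1:
        raise ValueError("sham_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fs = recording.eeg.fs
    x = recording.eeg.samples
    n = x.size
    half = int(round(2.0 * fs))

    trials: list[ClosedLoopTrial] = []
    n_dropped = 0
    for det in run_detector(recording.eeg, det_config):
        wireless = latency.draw_wireless(rng)
        sham = bool(rng.random() < sham_prob)
        i_det = int(round((det.time - recording.eeg.t0) * fs))
        if i_det + half > n:
            n_dropped += 1
            continue
        total = latency.algo_ms(det.used_tail) + wireless
        delay = phase_delay(
            det.fc, det.phase_at_fc, total, target_phase,
            latency.scheduling_resolution_ms,
        )
        plan = StimulusPlan(
            delay_ms=delay, tone_ms=tone_ms, target_phase=target_phase, sham=sham
        )
        if sham:
            achieved = float("nan")
        else:
            achieved = float(recording.true_phase_fn(det.time + delay / 1000.0))
        peri = x[max(0, i_det - half + 1) : i_det + half + 1]
        trials.append(
            ClosedLoopTrial(
                detection=det,
                plan=plan,
                peri_data=peri,
                achieved_phase=achieved,
                marker="red" if sham else "green",
            )
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} detection(s) within 2 s of the trace end "
            "(incomplete peri-detection buffer)",
            stacklevel=2,
        )
    return trials


def wrap_degrees(delta) -> np.ndarray:
    """Wrap angular differences into (-180, 180]."""
    return -((180.0 - np.asarray(delta, dtype=float)) % 360.0 - 180.0)


@dataclass(frozen=True)
class PhaseAccuracySummary:
    """Circular accuracy of the delivered (non-sham) tones."""

    mean_abs_error_deg: float
    circular_sd_deg: float
    n_stim: int
    n_sham: int
    table: pd.DataFrame = field(repr=False)


def evaluate_phase_accuracy(trials: Sequence[ClosedLoopTrial]) -> PhaseAccuracySummary:
    """Score achieved vs target phase over stimulation trials.

    Errors are circular: an achieved phase of 350° against a 0° target
    is a 10° error, not 350°.  Sham trials carry no tone and are
    excluded (but counted).
    """
    stim = [tr for tr in trials if not tr.plan.sham and np.isfinite(tr.achieved_phase)]
    n_sham = sum(tr.plan.sham for tr in trials)
    if not stim:
        raise NoStimTrialsError("no stimulation trials to summarize")
    errors = wrap_degrees(
        [tr.achieved_phase - tr.plan.target_phase for tr in stim]
    )
    table = pd.DataFrame(
        {
            "time_s": [tr.detection.time for tr in stim],
            "fc_hz": [tr.detection.fc for tr in stim],
            "used_tail": [tr.detection.used_tail for tr in stim],
            "delay_ms": [tr.plan.delay_ms for tr in stim],
            "achieved_phase_deg": [tr.achieved_phase for tr in stim],
            "error_deg": errors,
        }
    )
    circ_sd = float(np.degrees(spstats.circstd(np.deg2rad(errors))))
    return PhaseAccuracySummary(
        mean_abs_error_deg=float(np.mean(np.abs(errors))),
        circular_sd_deg=circ_sd,
        n_stim=len(stim),
        n_sham=int(n_sham),
        table=table,
    )
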