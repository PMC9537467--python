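"""Seeded synthetic overnight recordings with known ground truth.

Emulates what the implanted device sees across a night in a rodent:
alternating wake (low-amplitude broadband EEG, busy accelerometer) and
NREM epochs dominated by 0.5-4 Hz slow-wave (SW) activity, with the SW
amplitude slowly modulated at a configurable ultradian rate in
cycles/hour.  Because the SW component is rendered as an
amplitude-modulated sinusoid with a slowly drifting frequency, its
instantaneous phase is known analytically per sample — downstream
phase-locking accuracy can be scored against exact ground truth.

Everything is deterministic per seed: identical configs produce
bit-identical recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .traces import AxyTrace, EEGTrace

__all__ = [
    "SynthConfig",
    "SynthRecording",
    "make_sinusoid",
    "make_pink_noise",
    "make_overnight",
    "sinusoid_recording",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic overnight recording.

    Amplitudes are conventional rodent cortical values; the SW amplitude
    (peak, μV) is set well above the wake broadband RMS so that
    NREM/wake contrast mirrors a real nocturnal recording.

    Attributes
    ----------
    fs_eeg, fs_axy:
        EEG and accelerometer sampling rates, Hz.  The device samples
        biopotentials at 125 Hz and the accelerometer at 1 or 10 Hz.
    duration:
        Recording length in seconds.
    sw_band:
        Slow-wave band (Hz); SW carrier frequencies drift inside it.
    sw_amplitude:
        Peak amplitude of the SW sinusoid at modulation maximum, μV.
    wake_amplitude:
        RMS of the broadband wake EEG, μV.
    nrem_noise_uv:
        RMS of the residual broadband background during NREM, μV.
    noise_exponent:
        1/f slope of the broadband background (0 = white).
    cycle_rate:
        Ultradian modulation rate of SW power, cycles/hour; 0 disables
        the modulation.
    nrem_fraction:
        Long-run fraction of time asleep.
    mean_nrem_bout_s, min_bout_s:
        Semi-Markov sleep-architecture parameters: NREM bout lengths are
        exponential with this mean (floored at ``min_bout_s``); wake bout
        means are derived from ``nrem_fraction``.
    """

    duration: float
    fs_eeg: float = 125.0
    fs_axy: float = 1.0
    sw_band: tuple[float, float] = (0.5, 4.0)
    sw_amplitude: float = 150.0
    wake_amplitude: float = 30.0
    nrem_noise_uv: float = 15.0
    noise_exponent: float = 0.5
    cycle_rate: float = 3.0
    nrem_fraction: float = 0.75
    mean_nrem_bout_s: float = 300.0
    min_bout_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.nrem_fraction <= 1.0:
            raise ValueError("nrem_fraction must lie in [0, 1]")
        if self.cycle_rate < 0:
            raise ValueError("cycle_rate must be non-negative")
        lo, hi = self.sw_band
        if not 0 < lo < hi:
            raise ValueError("sw_band must be an increasing positive interval")
        if self.fs_eeg <= 2 * hi:
            raise ValueError("fs_eeg must exceed twice the upper SW band edge")
        if self.fs_axy not in (1.0, 10.0):
            raise ValueError("fs_axy must be 1 or 10 Hz (device options)")


@dataclass(frozen=True)
class SynthRecording:
    """A synthetic recording plus its ground truth.

    ``state_labels`` holds one flag per EEG sample (1 = NREM, 0 = wake).
    ``true_phase_fn`` maps time (s) to the instantaneous phase of the
    dominant SW component in degrees [0, 360); it returns NaN where no
    single SW sinusoid is active (wake, and the amplitude ramps at bout
    edges).
    """

    eeg: EEGTrace
    axy: AxyTrace
    state_labels: np.ndarray
    true_cycle_rate: float
    true_phase_fn: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if len(self.state_labels) != len(self.eeg):
            raise ValueError("label vector length must equal EEG length")

    def labels_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.eeg.times, "nrem": self.state_labels.astype(int)}
        ).to_csv(path, index=False)


def make_sinusoid(
    freq: float,
    amplitude: float,
    phase0: float = 0.0,
    duration: float = 2.0,
    fs: float = 125.0,
) -> EEGTrace:
    """A pure cosine test signal: ``amplitude·cos(2π·freq·t + phase0°)``.

    ``phase0`` is in degrees.  Used as the canonical noiseless input for
    detector and closed-loop trials.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq must lie in (0, fs/2), got {freq}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = amplitude * np.cos(2 * np.pi * freq * t + np.deg2rad(phase0))
    return EEGTrace(samples=samples, fs=fs)


def make_pink_noise(
    duration: float,
    fs: float,
    exponent: float = 1.0,
    rms: float = 1.0,
    seed: int = 0,
) -> EEGTrace:
    """Gaussian noise with a power-law spectrum ``S(f) ∝ f^-exponent``.

    Synthesized in the frequency domain (random phases, shaped
    magnitudes, zero DC) and rescaled so the output RMS equals ``rms``
    exactly.  Deterministic per seed.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    n = int(round(duration * fs))
    if rms == 0:
        return EEGTrace(samples=np.zeros(n), fs=fs)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mags = np.zeros_like(freqs)
    mags[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = mags * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(coeffs, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return EEGTrace(samples=x, fs=fs)


def sinusoid_recording(
    freq: float,
    amplitude: float,
    duration: float,
    fs: float = 125.0,
    phase0: float = 0.0,
) -> SynthRecording:
    """Wrap a pure sinusoid as a fully NREM-labeled recording.

    The analytic phase ``(phase0 + 360·freq·t) mod 360`` is exact at all
    times, which makes this the reference input for closed-loop phase
    accuracy scoring.
    """
    eeg = make_sinusoid(freq, amplitude, phase0=phase0, duration=duration, fs=fs)
    n_axy = int(round(duration * 1.0))
    axy = AxyTrace(
        x=np.zeros(n_axy), y=np.zeros(n_axy), z=np.zeros(n_axy), fs=1.0
    )

    def phase_fn(t):
        t = np.asarray(t, dtype=float)
        return (phase0 + 360.0 * freq * t) % 360.0

    return SynthRecording(
        eeg=eeg,
        axy=axy,
        state_labels=np.ones(len(eeg), dtype=np.uint8),
        true_cycle_rate=0.0,
        true_phase_fn=phase_fn,
    )


def _bout_schedule(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[int, float]]:
    """Two-state semi-Markov wake/NREM schedule as (state, duration_s) bouts.

    Exponential bout lengths, floored at ``min_bout_s``; the wake mean is
    set so the long-run NREM fraction matches ``nrem_fraction``.
    """
    f = cfg.nrem_fraction
    if f >= 1.0:
        return [(1, cfg.duration)]
    if f <= 0.0:
        return [(0, cfg.duration)]
    mean_nrem = cfg.mean_nrem_bout_s
    mean_wake = mean_nrem * (1.0 - f) / f
    bouts: list[tuple[int, float]] = []
    state = 1 if rng.random() < f else 0
    remaining = cfg.duration
    while remaining > 0:
        mean = mean_nrem if state == 1 else mean_wake
        dur = max(cfg.min_bout_s, rng.exponential(mean))
        dur = min(dur, remaining)
        bouts.append((state, dur))
        remaining -= dur
        state = 1 - state
    return bouts


def _drifting_phase(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample instantaneous frequency (Hz) and cumulative phase (deg).

    The frequency is a reflected random walk on 10-s control points,
    kept inside the central 80% of the band so the carrier never rides
    the band edges; phase is its cumulative integral.
    """
    lo, hi = band
    margin = 0.1 * (hi - lo)
    f_lo, f_hi = lo + margin, hi - margin
    n_ctrl = max(2, int(np.ceil(n / fs / 10.0)) + 1)
    steps = rng.normal(0.0, 0.08, size=n_ctrl)
    walk = np.cumsum(steps) + rng.uniform(f_lo, f_hi)
    # reflect into [f_lo, f_hi]
    span = f_hi - f_lo
    walk = np.abs((walk - f_lo) % (2 * span) - span) + f_lo - span
    walk = np.where(walk < f_lo, 2 * f_lo - walk, walk)
    t_ctrl = np.arange(n_ctrl) * 10.0
    t = np.arange(n) / fs
    freq = np.interp(t, t_ctrl, walk)
    phase0 = rng.uniform(0.0, 360.0)
    phase_deg = phase0 + 360.0 * np.cumsum(freq) / fs
    return freq, phase_deg


def _edge_ramp(labels: np.ndarray, fs: float, ramp_s: float = 1.0) -> np.ndarray:
    """Raised-cosine gate easing bout transitions over ``ramp_s`` seconds."""
    w = max(1, int(round(ramp_s * fs)))
    kernel = np.hanning(2 * w + 1)
    kernel /= kernel.sum()
    return np.convolve(labels.astype(float), kernel, mode="same")


def make_overnight(config: SynthConfig) -> SynthRecording:
    """Generate a full synthetic overnight recording.

    NREM epochs carry an amplitude-modulated SW sinusoid (envelope
    ``0.5 + 0.5·cos`` at ``cycle_rate`` cycles/hour) on a low broadband
    floor; wake epochs carry broadband noise only; the accelerometer is
    quiet in NREM and busy (baseline jitter plus movement bursts) in
    wake.  Per-sample NREM labels and the analytic SW phase come along
    as ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_eeg
    n = int(round(cfg.duration * fs))

    if cfg.cycle_rate > 0 and cfg.duration < 3600.0 / cfg.cycle_rate:
        warnings.warn(
            "duration shorter than one SW-power modulation cycle; "
            "the cycle rate will not be resolvable",
            stacklevel=2,
        )

    # --- state labels ---------------------------------------------------
    bouts = _bout_schedule(cfg, rng)
    labels = np.zeros(n, dtype=np.uint8)
    idx = 0
    for state, dur in bouts:
        m = int(round(dur * fs))
        labels[idx : idx + m] = state
        idx += m
    labels = labels[:n]

    nrem_gate = _edge_ramp(labels, fs)
    wake_gate = 1.0 - nrem_gate

    # --- SW component with analytic phase -------------------------------
    t = np.arange(n) / fs
    freq, phase_deg = _drifting_phase(n, fs, cfg.sw_band, rng)
    if cfg.cycle_rate > 0:
        envelope = 0.5 + 0.5 * np.cos(2 * np.pi * cfg.cycle_rate / 3600.0 * t)
    else:
        envelope = np.ones(n)
    sw = cfg.sw_amplitude * envelope * nrem_gate * np.cos(np.deg2rad(phase_deg))

    # --- broadband background -------------------------------------------
    noise = make_pink_noise(
        duration=n / fs, fs=fs, exponent=cfg.noise_exponent, rms=1.0,
        seed=int(rng.integers(2**31)),
    ).samples[:n]
    noise_scale = cfg.wake_amplitude * wake_gate + cfg.nrem_noise_uv * nrem_gate
    eeg_samples = sw + noise_scale * noise
    eeg = EEGTrace(samples=eeg_samples, fs=fs)

    # --- accelerometer ---------------------------------------------------
    n_axy = int(round(cfg.duration * cfg.fs_axy))
    axy_idx = np.minimum((np.arange(n_axy) / cfg.fs_axy * fs).astype(int), n - 1)
    axy_wake = wake_gate[axy_idx]
    axes = []
    for _ in range(3):
        base = rng.normal(0.0, 0.01, size=n_axy)  # resting jitter, g
        active = rng.normal(0.0, 0.25, size=n_axy)
        bursts = (rng.random(n_axy) < 0.15) * rng.normal(0.0, 0.8, size=n_axy)
        axes.append(base + axy_wake * (active + bursts))
    axy = AxyTrace(x=axes[0], y=axes[1], z=axes[2], fs=cfg.fs_axy)

    # --- ground-truth phase ----------------------------------------------
    # Defined only where the SW sinusoid is fully on (gate ≈ 1); NaN at
    # wake and inside the bout-edge ramps.
    defined = nrem_gate > 0.999
    phase_unwrapped = phase_deg.copy()

    def phase_fn(query_t):
        q = np.atleast_1d(np.asarray(query_t, dtype=float))
        ph = np.interp(q, t, phase_unwrapped) % 360.0
        near = np.clip(np.round(q * fs).astype(int), 0, n - 1)
        ph = np.where(defined[near], ph, np.nan)
        return ph if np.ndim(query_t) else float(ph[0])

    return SynthRecording(
        eeg=eeg,
        axy=axy,
        state_labels=labels,
        true_cycle_rate=cfg.cycle_rate,
        true_phase_fn=phase_fn,
    )
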