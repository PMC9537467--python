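"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: direct DFT sums instead of an FFT, hand-rolled
normal equations for the cosine fit, and an explicit difference-equation
loop for the filter cascade.  Nothing here shares code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

import biologger as bl


def dft_magnitudes(x: np.ndarray, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    """|DFT| on the buffer grid via explicit complex sums (zero-padded)."""
    padded = np.concatenate([x, np.zeros(n_grid - x.size)])
    n = np.arange(n_grid)
    ks = np.arange(n_grid // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(ks, n) / n_grid)
    return ks, np.abs(basis @ padded)


def brute_spectrum(x: np.ndarray, config: bl.DetectorConfig):
    """(fc, phase_deg, sw_power, ref_power) recomputed from first principles."""
    nbuf = config.buffer_n
    ks, mags = dft_magnitudes(np.asarray(x, float), nbuf)
    freqs = ks * config.fs / nbuf
    lo, hi = config.fc_search_band
    candidates = [k for k in ks if lo <= freqs[k] <= hi and freqs[k] > 0]
    kc = max(candidates, key=lambda k: mags[k])
    fc = freqs[kc]

    # Normal equations for x ≈ a·cos(2πfc·t) + b·sin(2πfc·t), t=0 at the end.
    t = (np.arange(len(x)) - (len(x) - 1)) / config.fs
    c, s = np.cos(2 * np.pi * fc * t), np.sin(2 * np.pi * fc * t)
    m = np.array([[c @ c, c @ s], [c @ s, s @ s]])
    a, b = np.linalg.solve(m, np.array([c @ x, s @ x]))
    phase = np.degrees(np.arctan2(-b, a)) % 360.0

    def band_power(band):
        sel = [k for k in ks if band[0] <= freqs[k] <= band[1]]
        p = mags[sel] ** 2 if config.power_def == "squared_magnitude" else mags[sel]
        return float(np.sum(p))

    return fc, phase, band_power(config.sw_band), band_power(config.ref_band)


def brute_filtered_max(x: np.ndarray, config: bl.DetectorConfig) -> float:
    """Causal Butterworth band-pass via an explicit per-sample loop."""
    sos = sps.butter(
        config.filter_order // 2, config.sw_band, btype="bandpass",
        fs=config.fs, output="sos",
    )
    y = np.asarray(x, float).copy()
    for b0, b1, b2, a0, a1, a2 in sos:
        out = np.empty_like(y)
        x1 = x2 = y1 = y2 = 0.0
        for i, xi in enumerate(y):
            yi = (b0 * xi + b1 * x1 + b2 * x2 - a1 * y1 - a2 * y2) / a0
            x2, x1 = x1, xi
            y2, y1 = y1, yi
            out[i] = yi
        y = out
    return float(np.max(np.abs(y[len(y) // 2 :])))


def brute_detect(x: np.ndarray, config: bl.DetectorConfig):
    """Gate-by-gate recomputation of the cascade.

    Returns (decision, gates, fc, phase, used_tail) where ``gates`` maps
    gate names to booleans for the path that produced the decision.
    """

    def gates_for(window):
        fc, phase, swp, refp = brute_spectrum(window, config)
        g = {
            "fc_band": config.sw_band[0] <= fc <= config.sw_band[1],
            "power_ratio": (swp / refp if refp > 0 else np.inf) >= config.ratio_threshold,
            "amplitude": brute_filtered_max(window, config) >= config.amplitude_threshold,
        }
        return fc, phase, g

    fc, phase, g = gates_for(x)
    if not all(g.values()):
        return False, g, fc, phase, False
    if fc > config.fc_rerun_cutoff:
        fc, phase, g = gates_for(np.asarray(x)[-config.tail_n:])
        return all(g.values()), g, fc, phase, True
    return True, g, fc, phase, False
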