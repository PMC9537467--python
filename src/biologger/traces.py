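"""Sampled-signal containers for biologger recordings.

Two channels of interest: a single-channel biopotential (EEG) trace in
microvolts sampled at 125 Hz by a 24-bit front end, and a tri-axial
accelerometer trace sampled at 1 or 10 Hz.  Both are thin frozen wrappers
around numpy arrays with the sampling metadata the rest of the package
needs (sampling rate, start time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EEGTrace", "AxyTrace", "DEFAULT_UV_PER_LSB"]

#: Default quantization gain of the analog front end, microvolts per least
#: significant bit.  ±300 μV signals sit far inside the signed 24-bit range
#: at this gain (full scale ±838 860.7 μV).
DEFAULT_UV_PER_LSB: float = 0.1

_INT24_MAX = 2**23 - 1
_INT24_MIN = -(2**23)


@dataclass(frozen=True)
class EEGTrace:
    """A uniformly sampled biopotential trace.

    Parameters
    ----------
    samples:
        Signal in microvolts.
    fs:
        Sampling rate in Hz (the device records at 125 Hz).
    t0:
        Time of the first sample, seconds since session start.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("EEG samples must be finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds since session start."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def quantize(self, uv_per_lsb: float = DEFAULT_UV_PER_LSB) -> np.ndarray:
        """Quantize to signed 24-bit integer codes at ``uv_per_lsb`` gain.

        Raises ``OverflowError`` if any sample falls outside the 24-bit
        signed range — the front end would clip it.
        """
        codes = np.round(self.samples / uv_per_lsb).astype(np.int64)
        if codes.max(initial=0) > _INT24_MAX or codes.min(initial=0) < _INT24_MIN:
            raise OverflowError("samples exceed the signed 24-bit range at this gain")
        return codes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "uv": self.samples})

    def to_csv(self, path) -> None:
        """Write ``time_s,uv`` CSV."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EEGTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two samples to infer fs")
        fs = 1.0 / np.median(np.diff(t))
        return cls(samples=df["uv"].to_numpy(), fs=float(fs), t0=float(t[0]))


@dataclass(frozen=True)
class AxyTrace:
    """A tri-axial accelerometer trace in g-scaled units."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        z = np.asarray(self.z, dtype=np.float64)
        if not (x.size == y.size == z.size):
            raise ValueError("axis lengths differ")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.x.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "x": self.x, "y": self.y, "z": self.z}
        )

    def to_csv(self, path) -> None:
        """Write ``time_s,x,y,z`` CSV."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AxyTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        return cls(
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            z=df["z"].to_numpy(),
            fs=float(fs),
            t0=float(t[0]) if len(t) else 0.0,
        )
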