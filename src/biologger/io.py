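"""File I/O helpers: CSV trace files, EDF reading, recording directories."""

from __future__ import annotations

from pathlib import Path

from .synth import SynthRecording
from .traces import AxyTrace, EEGTrace

__all__ = ["read_eeg", "write_recording_dir"]


def read_eeg(path) -> EEGTrace:
    """Load an EEG trace from a ``time_s,uv`` CSV or an EDF file.

    EDF files are read through :mod:`mne` (first channel); values are
    converted from volts to microvolts.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data(picks=[0])[0] * 1e6
        return EEGTrace(samples=data, fs=float(raw.info["sfreq"]))
    return EEGTrace.from_csv(path)


def write_recording_dir(recording: SynthRecording, outdir) -> dict[str, Path]:
    """Write a synthetic recording as eeg/axy/labels CSVs; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "eeg": outdir / "eeg.csv",
        "axy": outdir / "axy.csv",
        "labels": outdir / "labels.csv",
    }
    recording.eeg.to_csv(paths["eeg"])
    recording.axy.to_csv(paths["axy"])
    recording.labels_to_csv(paths["labels"])
    return paths
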