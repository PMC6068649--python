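"""Sampled PPG waveform container and its plain-text interchange format.

A recording is a uniformly sampled photoplethysmogram from one finger probe,
tagged with the acquisition rate, the hand it came from, and whether it was
taken before or after the haemodialysis (HD) session.  On disk a recording is
a two-column CSV (``time_s, amplitude``) preceded by ``#``-prefixed metadata
lines so that a single file is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("left", "right")
PHASES = ("before_HD", "after_HD")


@dataclass(frozen=True)
class PpgRecording:
    """A single-channel PPG trace with acquisition metadata.

    Parameters
    ----------
    samples : array of float
        Signal amplitude in arbitrary units, one value per sample.
    rate : float
        Sampling rate in Hz (the acquisition hardware runs at 1 kHz).
    channel : {"left", "right"}
        Hand the probe was attached to.
    phase : {"before_HD", "after_HD"}
        Position of the recording relative to the dialysis session.
    subject_id : str
        Opaque subject identifier.
    """

    samples: np.ndarray
    rate: float = 1000.0
    channel: str = "left"
    phase: str = "before_HD"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or Inf")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return (self.samples.size - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray) -> "PpgRecording":
        """Copy of this recording carrying new sample values, same metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_recording(recording: PpgRecording, path: str | Path) -> None:
    """Write a recording as a metadata-headed two-column CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz: {recording.rate}\n")
        fh.write(f"# channel: {recording.channel}\n")
        fh.write(f"# phase: {recording.phase}\n")
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write("time_s,amplitude\n")
        for t, v in zip(recording.times, recording.samples):
            fh.write(f"{t:.6f},{v:.9g}\n")


def read_recording(path: str | Path) -> PpgRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, skiprows=n_header)
    return PpgRecording(
        samples=frame["amplitude"].to_numpy(dtype=float),
        rate=float(meta.get("rate_hz", 1000.0)),
        channel=meta.get("channel", "left"),
        phase=meta.get("phase", "before_HD"),
        subject_id=meta.get("subject_id", "S00"),
    )
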