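"""Reading, preprocessing and combining bed-sensor signals.

A bed-leg BCG recording is a set of up to four load-sensor channels
(S1..S4) sampled uniformly (nominally 200 Hz), optionally with a
synchronized reference pulse channel (REF, e.g. from a fingertip pulse
oximeter).  Preprocessing removes the respiration baseline with a
Butterworth band-pass (1–8.5 Hz by default) and rescales the signal to
the [-0.5, 0.5] range before template matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

CHANNEL_NAMES = ("S1", "S2", "S3", "S4")

__all__ = [
    "CHANNEL_NAMES",
    "Recording",
    "Signal1D",
    "read_recording",
    "write_recording",
    "read_beats",
    "write_beats",
    "bandpass",
    "normalize",
    "combine_channels",
]


class ParseError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, bad header)."""


@dataclass
class Signal1D:
    """A single uniformly sampled channel."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Length of the signal in seconds."""
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class Recording:
    """Multi-channel bed-sensor recording with an optional reference pulse.

    Parameters
    ----------
    channels
        Mapping from channel id (``S1``..``S4``) to sample array.  All
        channels must have identical length.
    sampling_rate
        Samples per second, nominally 200.
    reference
        Optional reference pulse waveform (same length and rate), used as
        the beat-timing ground truth in evaluation.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    reference: Optional[np.ndarray] = None
    subject_id: str = ""
    posture: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("recording must have at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            lengths.add(self.reference.size)
        if len(lengths) != 1:
            raise ValueError("all channels (and reference) must have equal length")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def read_recording(path: str | Path, sampling_rate: float) -> Recording:
    """Read a delimited-text recording.

    The file is comma-delimited with one header row naming the columns
    (a subset of ``S1,S2,S3,S4,REF``) and one row per sample.  The
    sampling rate is supplied by the caller; it is not stored in the file.

    Raises
    ------
    ParseError
        On ragged rows or non-numeric cells, citing the offending line
        number (1-based, header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    known = set(CHANNEL_NAMES) | {"REF"}
    bad = [c for c in df.columns if c not in known]
    if bad:
        raise ParseError(f"{path}: unknown column(s) {bad}; expected subset of S1,S2,S3,S4,REF")
    numeric: dict[str, np.ndarray] = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_rows = converted.index[converted.isna() & df[col].notna()]
        if len(bad_rows) > 0:
            # +2: one for the header row, one for 0-based indexing
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r} at line {bad_rows[0] + 2}"
            )
        if converted.isna().any():
            missing = converted.index[converted.isna()][0]
            raise ParseError(f"{path}: missing cell in column {col!r} at line {missing + 2}")
        numeric[col] = converted.to_numpy(dtype=float)
    reference = numeric.pop("REF", None)
    if not numeric:
        raise ParseError(f"{path}: no sensor channel columns present")
    return Recording(channels=numeric, sampling_rate=sampling_rate, reference=reference)


def write_recording(path: str | Path, recording: Recording) -> None:
    """Write a recording back to the CSV layout accepted by :func:`read_recording`."""
    cols = {k: recording.channels[k] for k in CHANNEL_NAMES if k in recording.channels}
    # preserve any non-standard ordering for channels outside S1..S4
    for k, v in recording.channels.items():
        cols.setdefault(k, v)
    if recording.reference is not None:
        cols["REF"] = recording.reference
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_beats(path: str | Path) -> np.ndarray:
    """Read a beat-annotation file: one beat time (seconds) per line."""
    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric beat time at line {lineno}") from exc
    return np.asarray(times, dtype=float)


def write_beats(path: str | Path, beat_times: np.ndarray) -> None:
    """Write beat times, one per line, with 6 decimal places."""
    with open(path, "w") as fh:
        for t in np.asarray(beat_times, dtype=float):
            fh.write(f"{t:.6f}\n")


def bandpass(sig: Signal1D, low: float = 1.0, high: float = 8.5) -> Signal1D:
    """Zero-phase Butterworth band-pass filter.

    A second-order Butterworth band-pass applied forward and backward
    (``sosfiltfilt``), so the effective magnitude response is squared and
    the phase response is zero.  Zero phase matters here because peak
    timing drives the RR-interval accuracy downstream; a causal filter
    would bias every detected beat by its group delay.

    Parameters
    ----------
    low, high
        Pass-band edges in Hz, defaults 1.0 and 8.5.  The lower edge
        removes the respiration baseline; the upper edge removes
        high-frequency sensor noise while keeping the heartbeat wavelet.
    """
    nyq = sig.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq} Hz); got {low}, {high}"
        )
    sos = sps.butter(2, [low, high], btype="bandpass", fs=sig.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples)
    return Signal1D(filtered, sig.sampling_rate)


def normalize(sig: Signal1D) -> Signal1D:
    """Min-max rescale so the minimum maps to -0.5 and the maximum to +0.5.

    A constant signal has an undefined min-max map; it is mapped to all
    zeros so that a silent channel does not abort a run.
    """
    x = sig.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return Signal1D(np.zeros_like(x), sig.sampling_rate)
    return Signal1D((x - lo) / (hi - lo) - 0.5, sig.sampling_rate)


_COMBINE_MODES = {
    "s1": ("S1",),
    "s2": ("S2",),
    "mean_s1_s2": ("S1", "S2"),
    "mean_all": CHANNEL_NAMES,
}


def combine_channels(recording: Recording, mode: str) -> Signal1D:
    """Select or average sensor channels.

    ``s1``/``s2`` return the raw channel; ``mean_s1_s2`` and ``mean_all``
    return the samplewise arithmetic mean of S1–S2 or of all four sensors.
    Averaging S1 and S2 is the best-performing configuration for beat
    detection; averaging all four suffers from inter-sensor phase shifts.
    """
    try:
        wanted = _COMBINE_MODES[mode]
    except KeyError:
        raise ValueError(f"unknown channel mode {mode!r}; choose from {sorted(_COMBINE_MODES)}")
    missing = [c for c in wanted if c not in recording.channels]
    if missing:
        raise ValueError(f"channel(s) {missing} required by mode {mode!r} are missing")
    stacked = np.vstack([recording.channels[c] for c in wanted])
    return Signal1D(stacked.mean(axis=0), recording.sampling_rate)
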