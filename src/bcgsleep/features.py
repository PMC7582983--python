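"""Per-epoch HRV features: mean RR, RR variability, and VLF/LF/HF powers.

Features are computed on a trailing-buffer scheme: a 5-minute
initialization period precedes the first scored epoch, and for epoch
``k`` (1-based) of length tau the analysis buffer spans
``init + k * tau`` seconds of recording.  Band powers are taken from
trailing slices of that buffer — the last 5 minutes for VLF, the last
25 s for LF, and the last 6 s for HF — so each band is estimated from
the shortest window its dynamics require, at the cost of spectral
resolution in the short windows.

Spectral estimates use the standard HRV tachogram: the RR series
linearly interpolated onto a uniform 4 Hz grid, mean-subtracted, then a
rectangular-taper periodogram normalized so that the bin powers sum to
the mean square of the tachogram (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bcgsleep.beats import RrSeries
from bcgsleep.io import Signal1D

__all__ = [
    "WindowScheme",
    "FeatureVector",
    "epoch_windows",
    "rr_stats",
    "tachogram",
    "band_power",
    "compute_features",
    "features_to_frame",
    "write_features",
    "read_features",
]

FEATURE_COLUMNS = ("epoch_index", "rr_mean", "rr_std", "vlf", "lf", "hf", "lf_hf")


@dataclass(frozen=True)
class WindowScheme:
    """Epoch length and band-window layout for feature extraction.

    ``tau`` is the scoring-epoch length in seconds (default 30, sensible
    range 30–270 in 30 s steps).  The band edges are the conventional
    HRV bands: VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz.
    """

    tau: float = 30.0
    init_duration: float = 300.0
    vlf_window: float = 300.0
    lf_window: float = 25.0
    hf_window: float = 6.0
    vlf_band: tuple[float, float] = (0.0033, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    resample_rate: float = 4.0
    single_window: bool = False  # use the full trailing VLF window for all bands

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1 s")
        for name in ("init_duration", "vlf_window", "lf_window", "hf_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for band in (self.vlf_band, self.lf_band, self.hf_band):
            if not (0 <= band[0] < band[1]):
                raise ValueError(f"band edges must increase: {band}")


@dataclass
class FeatureVector:
    """HRV features for one scored epoch."""

    epoch_index: int
    rr_mean: float
    rr_std: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float

    def as_array(self) -> np.ndarray:
        """Model-input features: (rr_mean, rr_std, vlf, lf_hf)."""
        return np.array([self.rr_mean, self.rr_std, self.vlf, self.lf_hf], dtype=float)


def epoch_windows(
    scheme: WindowScheme, epoch_index: int
) -> tuple[float, tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Buffer length and trailing band windows for one epoch.

    Returns ``(total_buffer, vlf, lf, hf)``: the total seconds of
    recording consumed by this epoch (``init + epoch_index * tau``) and
    the (start, end) of each band window, all ending at the buffer end.
    For tau=30, epoch 1: total 330 s, VLF (30, 330), LF (305, 330),
    HF (324, 330).
    """
    if epoch_index < 1:
        raise ValueError("epoch_index is 1-based and must be >= 1")
    total = scheme.init_duration + epoch_index * scheme.tau
    return (
        total,
        (total - scheme.vlf_window, total),
        (total - scheme.lf_window, total),
        (total - scheme.hf_window, total),
    )


def _in_window(rr: RrSeries, window: tuple[float, float]) -> np.ndarray:
    # half-open (start, end]: an interval closing exactly at a buffer end
    # belongs to that buffer's epoch, not the next one
    start, end = window
    return (rr.times > start) & (rr.times <= end)


def rr_stats(rr: RrSeries, window: tuple[float, float]) -> tuple[float, float]:
    """Mean and sample SD of RR values timestamped in (start, end].

    A single interval yields SD 0 by convention.
    """
    mask = _in_window(rr, window)
    vals = rr.rr[mask]
    if vals.size == 0:
        raise ValueError(f"no RR intervals in window [{window[0]}, {window[1]})")
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), std


def tachogram(
    rr: RrSeries, window: tuple[float, float], resample_rate: float = 4.0
) -> Signal1D:
    """Uniformly resampled, mean-subtracted RR series over a window.

    The (time, rr) points inside the window are linearly interpolated
    onto a grid of ``round(length * rate) + 1`` samples spanning the
    window (values held constant beyond the first/last point), then the
    mean is removed so the DC bin carries no power.
    """
    mask = _in_window(rr, window)
    t, v = rr.times[mask], rr.rr[mask]
    if t.size < 2:
        raise ValueError(
            f"need >= 2 RR intervals in window [{window[0]}, {window[1]}) for a tachogram"
        )
    length = window[1] - window[0]
    n = int(round(length * resample_rate)) + 1
    grid = window[0] + np.arange(n) / resample_rate
    resampled = np.interp(grid, t, v)
    return Signal1D(resampled - resampled.mean(), resample_rate)


def band_power(tach: Signal1D, band: tuple[float, float]) -> float:
    """Periodogram power in a frequency band.

    Rectangular taper; bin powers are normalized so their total equals
    the mean square of the input (Parseval).  The band is the half-open
    interval [low, high): a bin landing exactly on the upper edge
    belongs to the next band, so adjacent HRV bands never double-count.
    """
    low, high = band
    nyq = tach.sampling_rate / 2.0
    if not (0 <= low < high) or high > nyq + 1e-12:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}]")
    x = tach.samples
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # one-sided: double every bin that has a conjugate partner
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / tach.sampling_rate)
    if high >= nyq - 1e-12:
        # a band reaching Nyquist means "everything above low"
        mask = freqs >= low - 1e-12
    else:
        mask = (freqs >= low - 1e-12) & (freqs < high - 1e-12)
    return float(power[mask].sum())


def compute_features(
    rr: RrSeries, scheme: WindowScheme, epoch_index: int
) -> FeatureVector:
    """All HRV features for one epoch.

    Mean/SD of RR come from the epoch's own trailing tau window; VLF,
    LF and HF powers from their respective trailing windows.  The LF/HF
    ratio is +inf when the HF power is exactly zero (flagged by the
    caller; only a perfectly constant rhythm produces it).
    """
    total, vlf_w, lf_w, hf_w = epoch_windows(scheme, epoch_index)
    if scheme.single_window:
        lf_w = hf_w = vlf_w
    epoch_w = (total - scheme.tau, total)
    for name, window in (("epoch", epoch_w), ("vlf", vlf_w), ("lf", lf_w), ("hf", hf_w)):
        if not np.any(_in_window(rr, window)):
            raise ValueError(
                f"insufficient RR coverage for the {name} window "
                f"[{window[0]:.0f}, {window[1]:.0f}) of epoch {epoch_index}"
            )
    rr_mean, rr_std = rr_stats(rr, epoch_w)

    def _power(window: tuple[float, float], band: tuple[float, float]) -> float:
        try:
            tach = tachogram(rr, window, scheme.resample_rate)
        except ValueError:
            return 0.0  # a lone interval in a short window carries no variability
        return band_power(tach, band)

    vlf = _power(vlf_w, scheme.vlf_band)
    lf = _power(lf_w, scheme.lf_band)
    hf = _power(hf_w, scheme.hf_band)
    lf_hf = lf / hf if hf > 0 else float("inf")
    return FeatureVector(epoch_index, rr_mean, rr_std, vlf, lf, hf, lf_hf)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "epoch_index": f.epoch_index,
                "rr_mean": f.rr_mean,
                "rr_std": f.rr_std,
                "vlf": f.vlf,
                "lf": f.lf,
                "hf": f.hf,
                "lf_hf": f.lf_hf,
            }
            for f in features
        ],
        columns=list(FEATURE_COLUMNS),
    )


def write_features(path: str | Path, features: list[FeatureVector]) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {sorted(missing)}")
    return df
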