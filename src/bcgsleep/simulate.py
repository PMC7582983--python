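"""Ground-truthed synthetic inputs for the whole pipeline.

Two generators are provided.  :func:`simulate_bcg` emits a four-channel
bed-sensor recording with known beat times: each heartbeat contributes a
damped-oscillation wavelet (a Gaussian-windowed 7 Hz cosine, 0.3 s
support, inside the 1–8.5 Hz preprocessing passband), channels differ by
gain and a small delay (emulating the inter-sensor phase shift of real
bed-leg arrays), a respiration sinusoid rides underneath, and white
noise is added at a configurable SNR.  A clean impulse-like reference
pulse train stands in for the fingertip pulse oximeter.

:func:`simulate_sleep_night` inverts the staging model: stages evolve by
a sticky Markov chain and features are drawn from stage-conditional
Gaussians whose means are chosen so that the noise-free features
classify back to their stage.

Neither generator attempts physiological realism beyond what the
pipeline is sensitive to: there are no movement artifacts, no posture
changes, and the hypnogram bout structure is a first-order chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bcgsleep.beats import BeatSeries
from bcgsleep.io import Recording, write_recording, write_beats
from bcgsleep.staging import (
    STAGES,
    Hypnogram,
    StageParams,
    classify_epoch,
)

__all__ = [
    "BcgSimSpec",
    "SimOutput",
    "simulate_bcg",
    "simulate_sleep_night",
    "write_dataset",
]


@dataclass
class BcgSimSpec:
    """Parameters of one synthetic bed-sensor recording.

    Defaults describe a quiet 10-minute recording of a resting adult:
    60 bpm with 5 bpm beat-to-beat jitter, 0.25 Hz respiration, and
    10 dB wavelet-to-noise SNR per channel.  ``snr_db=None`` (or inf)
    disables the noise entirely.
    """

    duration: float = 600.0
    sampling_rate: float = 200.0
    mean_hr: float = 60.0
    hr_sd: float = 5.0
    respiration_freq: float = 0.25
    respiration_amplitude: float = 1.0
    snr_db: Optional[float] = 10.0
    channel_gains: tuple[float, float, float, float] = (1.0, 0.9, 0.7, 0.6)
    channel_delays: tuple[float, float, float, float] = (0.0, 0.005, 0.012, 0.018)
    seed: int = 0
    wavelet_freq: float = 7.0
    wavelet_support: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (30.0 < self.mean_hr < 180.0):
            raise ValueError("mean_hr must lie in (30, 180) bpm")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be nonnegative")
        if len(self.channel_gains) != 4 or len(self.channel_delays) != 4:
            raise ValueError("exactly 4 channel gains and delays required")
        if any(abs(d) >= 0.1 for d in self.channel_delays):
            raise ValueError("channel delays must be < 0.1 s")


@dataclass
class SimOutput:
    """A generated recording together with its ground-truth beat times."""

    recording: Recording
    true_beats: BeatSeries
    spec: BcgSimSpec


def _wavelet(offsets: np.ndarray, freq: float, support: float) -> np.ndarray:
    """Gaussian-windowed cosine; peak 1.0 at offset 0, ~zero beyond +-support/2."""
    sigma = support / 6.0  # +-3 sigma spans the support
    return np.exp(-0.5 * (offsets / sigma) ** 2) * np.cos(2 * np.pi * freq * offsets)


def _pulse(offsets: np.ndarray, width: float = 0.02) -> np.ndarray:
    return np.exp(-0.5 * (offsets / width) ** 2)


def _add_train(
    out: np.ndarray,
    beat_times: np.ndarray,
    fs: float,
    kernel,
    half_support: float,
) -> None:
    n = out.size
    for tb in beat_times:
        i0 = max(0, int(math.floor((tb - half_support) * fs)))
        i1 = min(n, int(math.ceil((tb + half_support) * fs)) + 1)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / fs
        out[i0:i1] += kernel(t - tb)


def simulate_bcg(spec: BcgSimSpec) -> SimOutput:
    """Generate a four-channel recording with known beat times.

    Beat-to-beat intervals are Gaussian around 60/mean_hr (SD converted
    from the bpm jitter, truncated at 0.4 s), each beat stamps a wavelet
    into every channel after that channel's gain and delay, respiration
    and white noise are added, and a clean reference pulse channel
    carries the ground truth.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    mean_rr = 60.0 / spec.mean_hr
    # d(rr)/d(hr) = -60/hr^2: convert bpm jitter to seconds of RR jitter
    rr_sd = 60.0 * spec.hr_sd / spec.mean_hr**2
    edge = max(spec.wavelet_support, 0.5)
    beats = []
    t = edge
    while t < spec.duration - edge:
        beats.append(t)
        rr = rng.normal(mean_rr, rr_sd)
        t += max(rr, 0.4)
    beat_times = np.asarray(beats)
    if beat_times.size < 2:
        raise ValueError("duration too short to contain two beats")

    n = int(round(spec.duration * fs))
    grid_t = np.arange(n) / fs
    resp = spec.respiration_amplitude * np.sin(2 * np.pi * spec.respiration_freq * grid_t)
    half = spec.wavelet_support / 2.0
    kernel = lambda off: _wavelet(off, spec.wavelet_freq, spec.wavelet_support)

    channels: dict[str, np.ndarray] = {}
    snr = spec.snr_db
    noiseless = snr is None or math.isinf(snr)
    for ch, gain, delay in zip(
        ("S1", "S2", "S3", "S4"), spec.channel_gains, spec.channel_delays
    ):
        train = np.zeros(n)
        _add_train(train, beat_times + delay, fs, kernel, half)
        train *= gain
        sig = train + resp
        if not noiseless:
            p_signal = float(np.mean(train**2))
            noise_sd = math.sqrt(p_signal / 10.0 ** (snr / 10.0))
            sig = sig + rng.normal(0.0, noise_sd, n)
        channels[ch] = sig

    reference = np.zeros(n)
    _add_train(reference, beat_times, fs, _pulse, 0.08)
    recording = Recording(
        channels=channels, sampling_rate=fs, reference=reference, subject_id=f"sim{spec.seed}"
    )
    return SimOutput(recording=recording, true_beats=BeatSeries(beat_times), spec=spec)


def _stage_means(
    params: StageParams, box: float = 15.0, margin_cap: float = 8.0
) -> dict[str, np.ndarray]:
    """Find, per stage, a standardized feature vector that classifies to it.

    For stage S, solve the linear program maximizing the margin m of S's
    linear score over every competitor, with features confined to
    ``[-box, box]`` and the margin capped (the cap keeps the solution in
    the interior rather than at an arbitrary corner).  Raises if some
    stage can never win the argmax — such parameters are degenerate and
    cannot anchor a stage-conditional generator.
    """
    from scipy.optimize import linprog

    means: dict[str, np.ndarray] = {}
    for s in STAGES:
        a_s, b_s = params.coefficients[s][0], params.coefficients[s][1:]
        rows, rhs = [], []
        for o in STAGES:
            if o == s:
                continue
            a_o, b_o = params.coefficients[o][0], params.coefficients[o][1:]
            # m - (b_s - b_o) . x <= a_s - a_o
            rows.append(np.concatenate([-(b_s - b_o), [1.0]]))
            rhs.append(a_s - a_o)
        res = linprog(
            c=[0.0, 0.0, 0.0, 0.0, -1.0],  # maximize margin m
            A_ub=np.vstack(rows),
            b_ub=np.asarray(rhs),
            bounds=[(-box, box)] * 4 + [(None, margin_cap)],
            method="highs",
        )
        if not res.success or res.x[-1] <= 0:
            raise ValueError(
                f"degenerate parameters: no feature vector classifies to stage {s}"
            )
        means[s] = res.x[:4]
    return means


def simulate_sleep_night(
    params: StageParams,
    n_epochs: int = 1000,
    stage_dwell: float = 10.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, Hypnogram]:
    """Simulate one night of staged epochs with matching features.

    Stages follow a sticky first-order Markov chain (self-transition
    ``1 - 1/stage_dwell``, default 0.9, i.e. mean bout length 10
    epochs; the stationary distribution is uniform).  Features live in
    the standardized space of ``params``: each epoch draws
    ``mean(stage) + noise_sd * N(0, I)`` where the stage means are
    chosen so the noise-free vector classifies back to its stage.  If
    ``params`` carries a standardization, draws are mapped back to raw
    feature units.

    Returns a feature table (epoch_index, rr_mean, rr_std, vlf, lf, hf,
    lf_hf) and the ground-truth :class:`Hypnogram`.
    """
    if n_epochs < 10:
        raise ValueError("n_epochs must be >= 10")
    if stage_dwell < 1:
        raise ValueError("stage_dwell must be >= 1 epoch")
    rng = np.random.default_rng(seed)
    means = _stage_means(params)
    p_stay = 1.0 - 1.0 / stage_dwell
    p_move = (1.0 - p_stay) / (len(STAGES) - 1)

    stages: list[str] = []
    state = int(rng.integers(len(STAGES)))
    feats = np.empty((n_epochs, 4))
    for i in range(n_epochs):
        stages.append(STAGES[state])
        z = means[STAGES[state]] + noise_sd * rng.standard_normal(4)
        feats[i] = z
        if rng.random() < p_stay:
            pass
        else:
            others = [j for j in range(len(STAGES)) if j != state]
            state = others[int(rng.integers(len(others)))]
    if params.feature_means is not None:
        feats = params.feature_means + params.feature_sds * feats
    df = pd.DataFrame(feats, columns=["rr_mean", "rr_std", "vlf", "lf_hf"])
    df.insert(0, "epoch_index", np.arange(1, n_epochs + 1))
    # keep the full feature-table schema: hf is a unit placeholder so lf/hf = lf_hf
    df["hf"] = 1.0
    df["lf"] = df["lf_hf"]
    df = df[["epoch_index", "rr_mean", "rr_std", "vlf", "lf", "hf", "lf_hf"]]
    return df, Hypnogram(stages=stages)


def write_dataset(directory: str | Path, sim: SimOutput) -> None:
    """Write a simulated recording, its truth annotations, and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_recording(directory / "recording.csv", sim.recording)
    write_beats(directory / "true_beats.txt", sim.true_beats.beat_times)
    spec_dict = asdict(sim.spec)
    spec_dict["channel_gains"] = list(spec_dict["channel_gains"])
    spec_dict["channel_delays"] = list(spec_dict["channel_delays"])
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"spec": spec_dict, "n_beats": len(sim.true_beats)}, fh, indent=2)
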