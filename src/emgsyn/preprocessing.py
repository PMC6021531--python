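"""Surface-EMG preprocessing: envelope extraction, trial trimming, epoching.

The envelope chain follows the standard synergy-analysis recipe: zero-phase
2nd-order Butterworth band-pass (5-400 Hz), per-channel demeaning, full-wave
rectification, amplitude normalisation by a single shared maximum (so the
relative contribution of each muscle is preserved), optional per-channel
unit-variance scaling, and a zero-phase 2nd-order Butterworth 5 Hz low-pass.
Fatiguing trials are analysed in five epochs of 5% of the trial length spaced
every 25% of trial time, each rebinned to 100 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "RawTrial",
    "EnvelopeConfig",
    "EpochedTrial",
    "envelope_chain",
    "trim_multidirectional",
    "epoch_fatiguing",
    "rebin",
    "EPOCH_START_FRACTIONS",
]

#: Start fraction of each of the five analysis epochs. Each epoch spans 5% of
#: the trial, so epoch centres sit at 2.5, 25, 50, 75 and 97.5% of trial time:
#: the first epoch uses the very start of the trial and the last epoch the very
#: end, matching first-vs-last-epoch fatigue comparisons.
EPOCH_START_FRACTIONS = (0.0, 0.2375, 0.475, 0.7125, 0.95)
EPOCH_LENGTH_FRACTION = 0.05


@dataclass
class RawTrial:
    """A raw multichannel EMG recording.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_channels)
        Raw EMG, arbitrary units.
    sampling_rate : float
        Sampling rate in Hz.
    channel_names : sequence of str, optional
        One label per channel.
    direction : ndarray, shape (3,), optional
        Unit vector of the force-target direction for this trial.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_names: Sequence[str] | None = None
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (samples x channels)")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EnvelopeConfig:
    """Parameters of the envelope-extraction chain.

    ``unit_variance=True`` reproduces the conventional chain in which each
    channel is scaled to unit variance before the final low-pass.  Note that
    this rescales the rows of any synergy weight matrix extracted downstream;
    pipelines that compare extracted weights against externally defined
    weights should disable it.
    """

    bandpass: tuple[float, float] = (5.0, 400.0)
    lowpass: float = 5.0
    filter_order: int = 2
    normalize: str = "max"  # "max" (shared trial maximum) or "none"
    unit_variance: bool = True


@dataclass
class EpochedTrial:
    """Five analysis epochs of a fatiguing trial.

    ``envelopes`` holds the 100-bin rebinned envelope of each epoch
    (non-negative); ``raw_segments`` holds the corresponding unprocessed
    signal slices for spectral/RMS analysis.
    """

    envelopes: list[np.ndarray]  # 5 arrays, each (100, n_channels)
    raw_segments: list[np.ndarray]  # 5 arrays, (epoch_samples, n_channels)
    epoch_fractions: list[tuple[float, float]]
    sampling_rate: float
    channel_names: Sequence[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.envelopes)


def _sos(kind: str, cutoff, order: int, fs: float):
    return signal.butter(order, cutoff, btype=kind, fs=fs, output="sos")


def envelope_chain(raw: RawTrial, config: EnvelopeConfig | None = None) -> np.ndarray:
    """Extract the EMG envelope from a raw trial.

    Steps, in order: zero-phase Butterworth band-pass; per-channel demean;
    full-wave rectification; division of all channels by the shared trial
    maximum (``normalize="max"``); optional per-channel unit-variance scaling;
    zero-phase Butterworth low-pass; clipping of low-pass ringing at zero.

    Returns
    -------
    ndarray, shape (n_samples, n_channels)
        Non-negative envelope.
    """
    config = config or EnvelopeConfig()
    fs = raw.sampling_rate
    if fs <= 2 * config.bandpass[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band-pass up to {config.bandpass[1]} Hz"
        )
    x = raw.signal
    x = signal.sosfiltfilt(_sos("bandpass", config.bandpass, config.filter_order, fs), x, axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    x = np.abs(x)
    if config.normalize == "max":
        m = x.max()
        if m <= 0:
            raise ValueError("degenerate input: trial has no activation")
        x = x / m
    elif config.normalize != "none":
        raise ValueError(f"unknown normalize mode {config.normalize!r}")
    if config.unit_variance:
        sd = x.std(axis=0)
        if np.any(sd <= 0):
            bad = np.flatnonzero(sd <= 0)
            raise ValueError(f"degenerate channel(s) {bad.tolist()}: zero variance")
        x = x / sd
    x = signal.sosfiltfilt(_sos("lowpass", config.lowpass, config.filter_order, fs), x, axis=0)
    return np.clip(x, 0.0, None)


def trim_multidirectional(
    raw: RawTrial,
    config: EnvelopeConfig | None = None,
    match_window: float = 2.0,
) -> np.ndarray:
    """Average the envelope over the central ``match_window`` seconds.

    For target-matching trials a single stable activation vector per trial is
    obtained by averaging the envelope over the intermediate 2 s of the hold
    period (the whole trial is taken as the hold period).

    Returns
    -------
    ndarray, shape (n_channels,)
        Per-channel mean envelope over the central window.
    """
    if raw.duration < match_window:
        raise ValueError(
            f"trial duration {raw.duration:.3f}s shorter than match window {match_window}s"
        )
    env = envelope_chain(raw, config)
    n = raw.n_samples
    half = int(round(match_window * raw.sampling_rate / 2))
    mid = n // 2
    lo, hi = max(0, mid - half), min(n, mid + half)
    return env[lo:hi].mean(axis=0)


def rebin(x: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Rebin a (samples x channels) array to ``n_bins`` rows by block means.

    When the sample count is not a multiple of ``n_bins`` the leftover samples
    are distributed one per bin starting from the first bin.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < n_bins:
        raise ValueError(f"cannot rebin {n} samples into {n_bins} bins")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))[:-1]
    sums = np.add.reduceat(x, edges, axis=0)
    return sums / sizes[:, None]


def epoch_fatiguing(
    raw: RawTrial,
    config: EnvelopeConfig | None = None,
    n_bins: int = 100,
) -> EpochedTrial:
    """Split a fatiguing trial into five epochs with rebinned envelopes.

    Epochs are 5%-of-trial windows starting at 0, 23.75, 47.5, 71.25 and 95%
    of trial time; each epoch's envelope is rebinned to ``n_bins`` rows and
    the raw (unprocessed) samples are retained for spectral analysis.
    """
    n = raw.n_samples
    epoch_len = int(round(EPOCH_LENGTH_FRACTION * n))
    if epoch_len < n_bins:
        raise ValueError(
            f"trial too short: epoch of {epoch_len} samples cannot fill {n_bins} bins"
        )
    env = envelope_chain(raw, config)
    starts = [int(round(f * n)) for f in EPOCH_START_FRACTIONS]
    starts[-1] = n - epoch_len  # last epoch ends exactly at trial end
    envelopes, raw_segments, fractions = [], [], []
    for s in starts:
        e = s + epoch_len
        envelopes.append(rebin(env[s:e], n_bins))
        raw_segments.append(raw.signal[s:e].copy())
        fractions.append((s / n, e / n))
    return EpochedTrial(
        envelopes=envelopes,
        raw_segments=raw_segments,
        epoch_fractions=fractions,
        sampling_rate=raw.sampling_rate,
        channel_names=list(raw.channel_names or []),
    )
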