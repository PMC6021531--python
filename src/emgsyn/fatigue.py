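"""EMG fatigue metrics: Welch median frequency and RMS amplitude per epoch.

Myoelectric fatigue compresses the EMG power spectrum (the median frequency
declines) while the amplitude changes inconsistently.  Metrics are computed
on band-pass-filtered, demeaned raw epoch segments — not on envelopes, whose
5 Hz low-pass destroys the spectral content — and normalised to the first
epoch (first epoch = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import EpochedTrial

__all__ = [
    "FatigueMetrics",
    "median_frequency",
    "rms",
    "normalize_to_epoch1",
    "epoch_fatigue_metrics",
    "dominant_muscle",
]


def median_frequency(
    segment: np.ndarray,
    sampling_rate: float,
    window_seconds: float = 1.0,
    overlap: float = 0.5,
) -> float:
    """Median frequency of the Welch power spectrum, in Hz.

    Welch PSD with a Hann window (default 1 s segments, 50% overlap); the
    median is the frequency where cumulative power first reaches half the
    total power, with linear interpolation between frequency bins.
    """
    x = np.asarray(segment, dtype=float).ravel()
    nperseg = int(round(window_seconds * sampling_rate))
    noverlap = int(round(overlap * nperseg))
    if len(x) < 2 * nperseg - noverlap:
        raise ValueError(
            f"segment of {len(x)} samples too short for two Welch windows of {nperseg}"
        )
    freqs, psd = sps.welch(x, fs=sampling_rate, window="hann",
                           nperseg=nperseg, noverlap=noverlap)
    total = psd.sum()
    if total <= 0:
        raise ValueError("zero-power segment: median frequency undefined")
    cum = np.cumsum(psd)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(freqs[0])
    # linear interpolation within bin i
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(freqs[i - 1] + frac * (freqs[i] - freqs[i - 1]))


def rms(segment: np.ndarray) -> float:
    """Root-mean-square amplitude of the demeaned segment."""
    x = np.asarray(segment, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty segment")
    x = x - x.mean()
    return float(np.sqrt(np.mean(x**2)))


def normalize_to_epoch1(values: np.ndarray) -> np.ndarray:
    """Express per-epoch values as a percentage of the first epoch's value."""
    v = np.asarray(values, dtype=float)
    first = v[..., 0]
    if np.any(first <= 0):
        raise ValueError("first-epoch value must be positive for normalisation")
    return v * 100.0 / first[..., None]


@dataclass
class FatigueMetrics:
    """Per-epoch, per-channel fatigue parameters of one fatiguing trial."""

    median_frequency: np.ndarray   # (n_channels, n_epochs), Hz
    rms: np.ndarray                # (n_channels, n_epochs)
    mf_normalized: np.ndarray      # % of epoch 1
    rms_normalized: np.ndarray     # % of epoch 1
    channel_names: list[str]
    borg: np.ndarray | None = None


def epoch_fatigue_metrics(
    epoched: EpochedTrial,
    bandpass: tuple[float, float] = (5.0, 400.0),
    window_seconds: float = 1.0,
    borg: np.ndarray | None = None,
) -> FatigueMetrics:
    """Median frequency and RMS for every channel and epoch of a trial.

    Raw epoch segments are zero-phase band-pass filtered (2nd-order
    Butterworth) and demeaned before spectral/RMS analysis.
    """
    fs = epoched.sampling_rate
    sos = sps.butter(2, bandpass, btype="bandpass", fs=fs, output="sos")
    n_ch = epoched.raw_segments[0].shape[1]
    n_ep = epoched.n_epochs
    mf = np.empty((n_ch, n_ep))
    amp = np.empty((n_ch, n_ep))
    for e, seg in enumerate(epoched.raw_segments):
        filt = sps.sosfiltfilt(sos, seg, axis=0)
        filt = filt - filt.mean(axis=0, keepdims=True)
        for ch in range(n_ch):
            mf[ch, e] = median_frequency(filt[:, ch], fs, window_seconds)
            amp[ch, e] = rms(filt[:, ch])
    return FatigueMetrics(
        median_frequency=mf,
        rms=amp,
        mf_normalized=normalize_to_epoch1(mf),
        rms_normalized=normalize_to_epoch1(amp),
        channel_names=list(epoched.channel_names) or [f"ch{i}" for i in range(n_ch)],
        borg=borg,
    )


def dominant_muscle(weights: np.ndarray) -> np.ndarray:
    """Index of the highest-weight muscle for each synergy column."""
    return np.argmax(np.asarray(weights), axis=0)
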