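"""Synthetic multichannel surface EMG with planted synergy structure.

The generator emulates two isometric upper-limb task families used to study
muscle synergies and fatigue:

* a **multidirectional session** — one short target-matching trial per force
  direction, over the 26 directions evenly distributed around a sphere (the
  normalized non-zero vectors of the {-1,0,1}^3 lattice);
* a **fatiguing trial** — one long contraction held in a single synergy's
  preferred direction (PD), with linearly declining activation amplitude and
  linearly compressing power spectrum, while the synergy weight structure W
  stays constant (structure conservation is the planted truth).

The signal model is an amplitude-modulated band-limited Gaussian carrier: the
per-channel envelope expectation equals ``W @ c`` where ``c`` comes from a
rectified-cosine directional tuning law ``c_r = gain_r * max(0, d . PD_r)``.
The carrier is normalised so that its expected rectified value is 1, making
the planted envelope directly recoverable from the rectified signal mean.
Spectral compression is realised by time-warping the carrier, which scales
the instantaneous spectrum (and hence the median frequency) by the local
warp rate without touching the amplitude statistics.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .preprocessing import RawTrial

__all__ = [
    "GroundTruth",
    "SimConfig",
    "MUSCLE_NAMES",
    "default_ground_truth",
    "generate_direction_set",
    "tuned_activation",
    "simulate_multidirectional_session",
    "simulate_fatiguing_trial",
    "synthetic_borg",
]

#: Short names of the 14 recorded shoulder/arm/forearm muscles: superior and
#: middle trapezius, infraspinatus, serratus anterior, anterior/middle/
#: posterior deltoid, pectoralis major, short and long biceps heads, long and
#: lateral triceps heads, extensor and flexor carpi radialis.
MUSCLE_NAMES = (
    "ST", "MT", "Inf", "SA", "AD", "MD", "PDel",
    "PM", "BS", "BL", "TL", "TLat", "ECR", "FCR",
)


@dataclass
class GroundTruth:
    """Planted truth of a simulated participant.

    Attributes
    ----------
    weights : ndarray, shape (n_muscles, n_synergies)
        Non-negative synergy weight matrix W; each column unit-normalized.
    preferred_directions : ndarray, shape (n_synergies, 3)
        Unit 3-vector PD of each synergy.
    tuning_gain : ndarray, shape (n_synergies,)
        Peak activation coefficient of each synergy (at its PD).
    fatigue_decay : ndarray, shape (n_synergies,)
        Terminal activation as a fraction of the initial one, in (0, 1];
        the activation coefficient declines linearly to this fraction.
    spectral_compression : float
        Terminal carrier-band centre frequency as a fraction of the initial
        one, in (0, 1].
    """

    weights: np.ndarray
    preferred_directions: np.ndarray
    tuning_gain: np.ndarray
    fatigue_decay: np.ndarray
    spectral_compression: float = 0.9

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.preferred_directions = np.asarray(self.preferred_directions, dtype=float)
        self.tuning_gain = np.atleast_1d(np.asarray(self.tuning_gain, dtype=float))
        self.fatigue_decay = np.atleast_1d(np.asarray(self.fatigue_decay, dtype=float))
        if np.any(self.weights < 0):
            raise ValueError("synergy weights must be non-negative")
        norms = np.linalg.norm(self.weights, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("each weight column must have unit Euclidean norm")
        pd_norms = np.linalg.norm(self.preferred_directions, axis=1)
        if not np.allclose(pd_norms, 1.0, atol=1e-8):
            raise ValueError("preferred directions must be unit vectors")
        if np.any(self.tuning_gain < 0):
            raise ValueError("tuning gains must be non-negative")
        for name, frac in (("fatigue_decay", self.fatigue_decay),
                           ("spectral_compression", np.atleast_1d(self.spectral_compression))):
            if np.any(frac <= 0) or np.any(frac > 1):
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def n_muscles(self) -> int:
        return self.weights.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.weights.shape[1]


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults mirror the study conditions the generator emulates: 14 muscles,
    3 synergies, 2000 Hz sampling, a 20-200 Hz EMG carrier band, 4 s
    target-matching holds, 270 s (4.5 min, the mean time to fatigue)
    fatiguing contractions, and 30 dB envelope-scale SNR.
    """

    n_muscles: int = 14
    n_synergies: int = 3
    sampling_rate: float = 2000.0
    trial_duration: float = 4.0       # multidirectional hold, seconds
    fatigue_duration: float = 270.0   # fatiguing contraction, seconds
    carrier_band: tuple[float, float] = (20.0, 200.0)
    noise_snr: float = 30.0           # dB, modulated power vs additive noise power
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.carrier_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper carrier band")
        if self.n_synergies >= self.n_muscles:
            raise ValueError("n_synergies must be smaller than n_muscles")


def default_ground_truth() -> GroundTruth:
    """Canonical 14-muscle, 3-synergy planted truth.

    The three synergies mimic the functional groupings seen in isometric
    upper-limb tasks: an external-rotation synergy dominated by the middle
    trapezius and infraspinatus, a flexion synergy dominated by the anterior
    deltoid, pectoralis major and short biceps head, and an extension synergy
    dominated by the triceps heads.  Their preferred directions are well
    separated (> 75 degrees pairwise).  Fatigue defaults plant a 24.5%
    activation decrease and a 10% spectral compression over the trial.
    """
    raw = np.array([
        # S1 ext-rot  S2 flexion  S3 extension
        [0.50,        0.05,       0.20],   # ST
        [1.00,        0.05,       0.05],   # MT
        [0.90,        0.05,       0.10],   # Inf
        [0.20,        0.30,       0.05],   # SA
        [0.05,        1.00,       0.05],   # AD
        [0.30,        0.20,       0.30],   # MD
        [0.10,        0.05,       0.50],   # PDel
        [0.05,        0.90,       0.05],   # PM
        [0.05,        0.80,       0.05],   # BS
        [0.10,        0.50,       0.10],   # BL
        [0.05,        0.05,       0.90],   # TL
        [0.05,        0.05,       1.00],   # TLat
        [0.60,        0.10,       0.50],   # ECR
        [0.05,        0.30,       0.10],   # FCR
    ])
    weights = raw / np.linalg.norm(raw, axis=0, keepdims=True)
    pds = np.array([
        [1.0, 0.6, 0.2],
        [-0.4, 0.5, 1.0],
        [0.3, -1.0, 0.4],
    ])
    pds = pds / np.linalg.norm(pds, axis=1, keepdims=True)
    return GroundTruth(
        weights=weights,
        preferred_directions=pds,
        tuning_gain=np.ones(3),
        fatigue_decay=np.full(3, 0.755),
        spectral_compression=0.9,
    )


def generate_direction_set(n_directions: int = 26) -> np.ndarray:
    """The 26 force-target directions evenly distributed around a sphere.

    These are the normalized non-zero vectors of the {-1, 0, 1}^3 lattice:
    the 6 face, 12 edge and 8 corner directions of a cube.  The set is closed
    under negation and sums to zero.

    Returns
    -------
    ndarray, shape (26, 3)
    """
    if n_directions != 26:
        raise ValueError(
            "only the canonical 26-direction set is generated; "
            "supply custom directions directly for other designs"
        )
    vecs = [
        np.array(v, dtype=float)
        for v in itertools.product((-1, 0, 1), repeat=3)
        if any(v)
    ]
    arr = np.array(vecs)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)


def tuned_activation(
    ground_truth: GroundTruth, synergy_index: int, direction: np.ndarray
) -> float:
    """Rectified-cosine directional tuning.

    The activation coefficient of synergy ``r`` for a force direction ``d``
    is ``gain_r * max(0, d . PD_r)``: maximal at the PD and zero for any
    direction at 90 degrees or more from it.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    pd = ground_truth.preferred_directions[synergy_index]
    return float(ground_truth.tuning_gain[synergy_index] * max(0.0, float(direction @ pd)))


def _band_limited_carrier(
    rng: Generator, n_samples: int, n_channels: int, fs: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Gaussian noise band-limited to ``band``, scaled so E|x| = 1 per channel."""
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=0)
    sd = x.std(axis=0)
    # E|N(0, sigma)| = sigma * sqrt(2/pi); rescale to sigma = sqrt(pi/2)
    return x / sd * np.sqrt(np.pi / 2.0)


def _noise_std(modulated: np.ndarray, snr_db: float) -> float:
    p_mod = float(np.mean(modulated**2))
    if p_mod <= 0:
        return 1e-6  # noise floor for an inactive trial
    return float(np.sqrt(p_mod * 10.0 ** (-snr_db / 10.0)))


def simulate_multidirectional_session(
    ground_truth: GroundTruth,
    directions: np.ndarray,
    config: SimConfig,
) -> list[RawTrial]:
    """Simulate one target-matching trial per force direction.

    Each trial's per-channel envelope expectation is ``W @ c(direction)``
    with ``c`` from :func:`tuned_activation`, realised as an
    amplitude-modulated band-limited Gaussian carrier plus additive white
    noise at the configured envelope-scale SNR.
    """
    directions = np.asarray(directions, dtype=float)
    n = int(round(config.trial_duration * config.sampling_rate))
    children = SeedSequence(config.seed).spawn(len(directions))
    trials = []
    for d, child in zip(directions, children):
        rng = default_rng(child)
        c = np.array([
            tuned_activation(ground_truth, r, d)
            for r in range(ground_truth.n_synergies)
        ])
        envelope = ground_truth.weights @ c  # (n_muscles,)
        carrier = _band_limited_carrier(
            rng, n, ground_truth.n_muscles, config.sampling_rate, config.carrier_band
        )
        s = carrier * envelope[None, :]
        sigma = _noise_std(s, config.noise_snr)
        x = s + sigma * rng.standard_normal(s.shape)
        trials.append(
            RawTrial(
                signal=x,
                sampling_rate=config.sampling_rate,
                channel_names=list(MUSCLE_NAMES[: ground_truth.n_muscles]),
                direction=d,
            )
        )
    return trials


def simulate_fatiguing_trial(
    ground_truth: GroundTruth,
    synergy_index: int,
    config: SimConfig,
) -> RawTrial:
    """Simulate a sustained contraction in one synergy's preferred direction.

    The exertion direction is the synergy's PD, so every synergy contributes
    according to its tuning at that direction.  Each synergy's activation
    declines linearly from its initial value to ``fatigue_decay`` times it
    over the trial; the carrier spectrum compresses linearly in time by the
    factor ``spectral_compression`` (via time-warping); the weight matrix W
    is constant throughout.
    """
    fs = config.sampling_rate
    n = int(round(config.fatigue_duration * fs))
    if int(0.05 * n) < 1:
        raise ValueError("fatigue_duration too short to resolve five epochs")
    rng = default_rng(SeedSequence([0 if config.seed is None else config.seed,
                                    17 + synergy_index]))
    d = ground_truth.preferred_directions[synergy_index]
    t_frac = np.arange(n) / n  # t / T

    # Per-synergy activation trajectories: linear decline to the decay fraction.
    c0 = np.array([
        tuned_activation(ground_truth, r, d)
        for r in range(ground_truth.n_synergies)
    ])
    profiles = 1.0 + (ground_truth.fatigue_decay[:, None] - 1.0) * t_frac[None, :]
    activations = c0[:, None] * profiles  # (n_synergies, n)
    envelope = (ground_truth.weights @ activations).T  # (n, n_muscles)

    # Spectral compression: time-warp a stationary carrier. The local warp
    # rate s(t) = 1 + (compression - 1) t/T scales the instantaneous spectrum
    # by s(t), so the epoch-wise median frequency tracks s at the epoch centre.
    carrier = _band_limited_carrier(
        rng, n, ground_truth.n_muscles, fs, config.carrier_band
    )
    rate = 1.0 + (ground_truth.spectral_compression - 1.0) * t_frac
    tau = np.concatenate(([0.0], np.cumsum(rate)))[:-1]  # warped sample index
    sample_grid = np.arange(n, dtype=float)
    warped = np.empty_like(carrier)
    for ch in range(carrier.shape[1]):
        warped[:, ch] = np.interp(tau, sample_grid, carrier[:, ch])

    s = warped * envelope
    sigma = _noise_std(s, config.noise_snr)
    x = s + sigma * rng.standard_normal(s.shape)
    return RawTrial(
        signal=x,
        sampling_rate=fs,
        channel_names=list(MUSCLE_NAMES[: ground_truth.n_muscles]),
        direction=d,
    )


def synthetic_borg(n_epochs: int = 5, start: float = 2.0, stop: float = 10.0) -> np.ndarray:
    """Synthetic CR10 perceived-exertion trajectory, rising linearly to task failure."""
    return np.linspace(start, stop, n_epochs)
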