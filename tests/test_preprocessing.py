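"""Envelope chain, trial trimming, epoching and rebinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsyn import (
    EnvelopeConfig,
    RawTrial,
    envelope_chain,
    epoch_fatiguing,
    rebin,
    trim_multidirectional,
)
from emgsyn.preprocessing import EPOCH_START_FRACTIONS

FS = 2000.0
RAW = EnvelopeConfig(normalize="none", unit_variance=False)


def carrier(rng, n, amplitude=1.0):
    """80 Hz sinusoid with random phase, a convenient in-band test signal."""
    t = np.arange(n) / FS
    return amplitude * np.sin(2 * np.pi * 80.0 * t + rng.uniform(0, 2 * np.pi))


class TestEnvelopeChain:
    def test_zero_signal_rejected(self):
        trial = RawTrial(np.zeros((4000, 2)), FS)
        with pytest.raises(ValueError):
            envelope_chain(trial)

    def test_low_sampling_rate_rejected(self):
        trial = RawTrial(np.random.default_rng(0).normal(size=(700, 1)), 700.0)
        with pytest.raises(ValueError):
            envelope_chain(trial)

    def test_proportional_channels_identical_after_unit_variance(self):
        rng = np.random.default_rng(0)
        x = carrier(rng, 8000)
        trial = RawTrial(np.column_stack([x, 3.7 * x]), FS)
        env = envelope_chain(trial, EnvelopeConfig())
        assert np.allclose(env[:, 0], env[:, 1], atol=1e-9)

    def test_sinusoid_rectified_mean(self):
        """The rectified mean of a sinusoid of amplitude A is 2A/pi."""
        A = 0.8
        n = int(10 * FS)
        t = np.arange(n) / FS
        trial = RawTrial(A * np.sin(2 * np.pi * 80.0 * t)[:, None], FS)
        env = envelope_chain(trial, RAW)
        assert env.mean() == pytest.approx(2 * A / np.pi, rel=0.02)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6000, 3)) * np.array([1.0, 0.4, 2.0])
        a = envelope_chain(RawTrial(x, FS))
        b = envelope_chain(RawTrial(123.4 * x, FS))
        assert np.allclose(a, b, atol=1e-9)

    def test_symmetric_burst_gives_symmetric_envelope(self):
        """Zero-phase filtering introduces no group delay."""
        n = int(4 * FS)
        t = np.arange(n) / FS
        window = np.exp(-0.5 * ((t - 2.0) / 0.3) ** 2)
        x = (window * np.sin(2 * np.pi * 80.0 * t))[:, None]
        env = envelope_chain(RawTrial(x, FS), RAW)[:, 0]
        centre = int(np.argmax(np.convolve(env, np.ones(101) / 101, mode="same")))
        assert abs(centre - n // 2) < 0.05 * FS

    def test_output_non_negative(self):
        rng = np.random.default_rng(2)
        env = envelope_chain(RawTrial(rng.normal(size=(5000, 4)), FS))
        assert env.min() >= 0.0


class TestTrimMultidirectional:
    def test_central_window_of_4s_hold(self):
        """A 4 s hold is averaged over [1 s, 3 s]."""
        rng = np.random.default_rng(3)
        n = int(4 * FS)
        x = carrier(rng, n)
        # mark the central window with a higher amplitude plateau
        amp = np.ones(n)
        amp[int(1 * FS):int(3 * FS)] = 2.0
        trial = RawTrial((amp * x)[:, None], FS)
        central = trim_multidirectional(trial, RAW)
        full = envelope_chain(trial, RAW).mean(axis=0)
        assert central[0] > 1.8 * (2 / np.pi) * 0.9
        assert central[0] > full[0]

    def test_stationary_central_mean_matches_global_mean(self):
        rng = np.random.default_rng(4)
        trial = RawTrial(carrier(rng, int(4 * FS))[:, None], FS)
        central = trim_multidirectional(trial, RAW)
        global_mean = envelope_chain(trial, RAW).mean(axis=0)
        assert central[0] == pytest.approx(global_mean[0], rel=0.02)

    def test_onset_transient_partially_excluded(self):
        """Central 2 s of a 4 s hold is closer to steady state than the full mean."""
        rng = np.random.default_rng(5)
        n = int(4 * FS)
        amp = np.ones(n)
        ramp = np.linspace(0.2, 1.0, int(1 * FS))
        amp[: int(1 * FS)] = ramp
        trial = RawTrial((amp * carrier(rng, n))[:, None], FS)
        central = trim_multidirectional(trial, RAW)[0]
        full = envelope_chain(trial, RAW).mean(axis=0)[0]
        steady = 2.0 / np.pi
        assert abs(central - steady) < abs(full - steady)

    def test_short_trial_rejected(self):
        trial = RawTrial(np.random.default_rng(6).normal(size=(int(1.5 * FS), 1)), FS)
        with pytest.raises(ValueError):
            trim_multidirectional(trial)


class TestRebin:
    def test_always_100_rows(self):
        rng = np.random.default_rng(7)
        for n in (100, 101, 937, 5000):
            assert rebin(rng.normal(size=(n, 3)), 100).shape == (100, 3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rebin(np.zeros((99, 2)), 100)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        mult=st.integers(min_value=1, max_value=13),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_mean_preserved_when_divisible(self, mult, seed):
        x = np.random.default_rng(seed).normal(size=(100 * mult, 2))
        assert np.allclose(rebin(x, 100).mean(axis=0), x.mean(axis=0), atol=1e-12)

    def test_leftover_samples_spread_from_first_bin(self):
        x = np.arange(103, dtype=float)[:, None]
        binned = rebin(x, 100)
        # first 3 bins average 2 samples, the rest hold 1 sample
        assert binned[0, 0] == pytest.approx(0.5)
        assert binned[2, 0] == pytest.approx(4.5)
        assert binned[3, 0] == pytest.approx(6.0)


class TestEpochFatiguing:
    def test_epoch_windows_arithmetic(self):
        """A 300 s trial yields 15 s epochs at [0, 15] ... [285, 300] s."""
        rng = np.random.default_rng(8)
        fs = 1000.0
        n = int(300 * fs)
        trial = RawTrial(rng.normal(size=(n, 2)), fs)
        ep = epoch_fatiguing(trial, RAW)
        assert ep.n_epochs == 5
        assert all(env.shape == (100, 2) for env in ep.envelopes)
        assert all(seg.shape[0] == int(0.05 * n) for seg in ep.raw_segments)
        assert ep.epoch_fractions[0] == pytest.approx((0.0, 0.05), abs=1e-9)
        assert ep.epoch_fractions[-1] == pytest.approx((0.95, 1.0), abs=1e-9)
        for frac, start in zip(ep.epoch_fractions[1:4], EPOCH_START_FRACTIONS[1:4]):
            assert frac[0] == pytest.approx(start, abs=1e-6)

    def test_ramp_amplitude_gives_expected_epoch_means(self):
        """Linear 0->1 amplitude ramp: epoch means track 2.5/25/50/75/97.5%."""
        rng = np.random.default_rng(9)
        fs = 1000.0
        n = int(200 * fs)
        amp = np.linspace(0.0, 1.0, n)
        x = amp * rng.normal(size=n)
        ep = epoch_fatiguing(RawTrial(x[:, None], fs), RAW)
        means = np.array([env.mean() for env in ep.envelopes])
        expected = np.array([0.025, 0.25, 0.50, 0.75, 0.975])
        assert np.allclose(means / means[2], expected / 0.5, atol=0.06)

    def test_trial_too_short_rejected(self):
        trial = RawTrial(np.random.default_rng(10).normal(size=(1500, 1)), FS)
        with pytest.raises(ValueError):
            epoch_fatiguing(trial, RAW)

    def test_envelopes_non_negative(self):
        rng = np.random.default_rng(11)
        trial = RawTrial(rng.normal(size=(int(10 * FS), 2)), FS)
        ep = epoch_fatiguing(trial, RAW)
        assert all(env.min() >= 0 for env in ep.envelopes)
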