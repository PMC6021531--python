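"""Generator correctness: direction set geometry, tuning law, planted signals."""

import numpy as np
import pytest

from emgsyn import (
    EnvelopeConfig,
    GroundTruth,
    SimConfig,
    envelope_chain,
    generate_direction_set,
    simulate_fatiguing_trial,
    simulate_multidirectional_session,
    tuned_activation,
)
from emgsyn.fatigue import median_frequency
from emgsyn.study import ANALYSIS_ENVELOPE

RAW_ENVELOPE = EnvelopeConfig(normalize="none", unit_variance=False)


def small_truth() -> GroundTruth:
    w = np.array([[1.0, 0.1], [0.2, 1.0], [0.1, 0.5], [0.6, 0.1]])
    w /= np.linalg.norm(w, axis=0)
    pds = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return GroundTruth(
        weights=w, preferred_directions=pds, tuning_gain=[1.0, 1.0],
        fatigue_decay=[0.8, 0.8], spectral_compression=0.9,
    )


class TestDirectionSet:
    def test_canonical_26_geometry(self):
        dirs = generate_direction_set(26)
        assert dirs.shape == (26, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        # all pairwise distinct
        assert len({tuple(np.round(d, 9)) for d in dirs}) == 26
        # closed under negation and symmetric: the set sums to zero
        assert np.allclose(dirs.sum(axis=0), 0.0, atol=1e-12)
        as_set = {tuple(np.round(d, 9)) for d in dirs}
        for d in dirs:
            assert tuple(np.round(-d, 9)) in as_set

    def test_unsupported_count_rejected(self):
        with pytest.raises(ValueError):
            generate_direction_set(12)


class TestTunedActivation:
    def test_rectified_cosine_values(self, ground_truth):
        pd0 = ground_truth.preferred_directions[0]
        assert tuned_activation(ground_truth, 0, pd0) == pytest.approx(
            ground_truth.tuning_gain[0]
        )
        # a direction orthogonal to the PD gives zero
        perp = np.cross(pd0, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        assert tuned_activation(ground_truth, 0, perp) == 0.0
        # 60 degrees from the PD gives cos(60) = 0.5
        d60 = np.cos(np.pi / 3) * pd0 + np.sin(np.pi / 3) * perp
        assert tuned_activation(ground_truth, 0, d60) == pytest.approx(0.5, abs=1e-12)

    def test_non_unit_direction_rejected(self, ground_truth):
        with pytest.raises(ValueError):
            tuned_activation(ground_truth, 0, np.array([1.0, 1.0, 0.0]))


class TestMultidirectionalSession:
    def test_seed_determinism(self):
        gt = small_truth()
        cfg = SimConfig(n_muscles=4, n_synergies=2, trial_duration=0.5, seed=5)
        dirs = generate_direction_set(26)[:4]
        a = simulate_multidirectional_session(gt, dirs, cfg)
        b = simulate_multidirectional_session(gt, dirs, cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.signal, tb.signal)

    def test_zero_gain_gives_noise_floor(self):
        gt = small_truth()
        gt.tuning_gain = np.zeros(2)
        cfg = SimConfig(n_muscles=4, n_synergies=2, trial_duration=0.5, seed=5)
        trials = simulate_multidirectional_session(
            gt, generate_direction_set(26)[:2], cfg
        )
        assert np.abs(trials[0].signal).max() < 1e-4

    def test_envelope_means_recover_planted_expectation(self, ground_truth):
        """Rectified-low-passed channel means regress on W @ c with slope ~ 1."""
        cfg = SimConfig(seed=3, trial_duration=2.0)
        dirs = generate_direction_set(26)
        trials = simulate_multidirectional_session(ground_truth, dirs, cfg)
        measured, expected = [], []
        for t in trials:
            env = envelope_chain(t, RAW_ENVELOPE)
            c = np.array([
                tuned_activation(ground_truth, r, t.direction) for r in range(3)
            ])
            measured.append(env.mean(axis=0))
            expected.append(ground_truth.weights @ c)
        x = np.concatenate(expected)
        y = np.concatenate(measured)
        slope = float(x @ y / (x @ x))
        assert abs(slope - 1.0) < 0.05

    def test_envelope_matrix_has_planted_rank(self, ground_truth):
        """SVD tail energy beyond the synergy count stays below 5%."""
        cfg = SimConfig(seed=4, trial_duration=2.0)
        dirs = generate_direction_set(26)
        trials = simulate_multidirectional_session(ground_truth, dirs, cfg)
        D = np.column_stack(
            [envelope_chain(t, RAW_ENVELOPE).mean(axis=0) for t in trials]
        )
        s = np.linalg.svd(D, compute_uv=False)
        tail = np.sum(s[ground_truth.n_synergies:] ** 2) / np.sum(s**2)
        assert tail < 0.05

    def test_envelopes_non_negative(self, ground_truth):
        cfg = SimConfig(seed=6, trial_duration=1.0)
        trial = simulate_multidirectional_session(
            ground_truth, generate_direction_set(26)[:1], cfg
        )[0]
        assert envelope_chain(trial, ANALYSIS_ENVELOPE).min() >= 0.0


class TestFatiguingTrial:
    def test_no_fatigue_limit_is_stationary(self):
        gt = small_truth()
        gt.fatigue_decay = np.ones(2)
        gt.spectral_compression = 1.0
        cfg = SimConfig(n_muscles=4, n_synergies=2, fatigue_duration=60.0, seed=7)
        trial = simulate_fatiguing_trial(gt, 0, cfg)
        n = trial.n_samples
        L = int(0.05 * n)
        env = np.abs(trial.signal)
        ratio = env[n - L:].mean() / env[:L].mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_planted_activation_decay_visible_in_envelope(self, ground_truth):
        """Epoch-V/epoch-I rectified-mean ratio tracks the planted 0.755 decay."""
        cfg = SimConfig(fatigue_duration=120.0, seed=8)
        trial = simulate_fatiguing_trial(ground_truth, 0, cfg)
        n = trial.n_samples
        L = int(0.05 * n)
        env = np.abs(trial.signal)
        ratio = env[n - L:].mean() / env[:L].mean()
        # linear decline to 0.755 sampled at the epoch centres (2.5% and 97.5%)
        expected = (1 - 0.245 * 0.975) / (1 - 0.245 * 0.025)
        assert ratio == pytest.approx(expected, abs=0.05)

    def test_planted_spectral_compression(self, ground_truth):
        """Channel-averaged epoch-V median frequency is ~90% of epoch I."""
        cfg = SimConfig(fatigue_duration=120.0, seed=9)
        trial = simulate_fatiguing_trial(ground_truth, 0, cfg)
        n = trial.n_samples
        L = int(0.05 * n)
        mf_first = np.mean([
            median_frequency(trial.signal[:L, ch], cfg.sampling_rate)
            for ch in range(trial.n_channels)
        ])
        mf_last = np.mean([
            median_frequency(trial.signal[n - L:, ch], cfg.sampling_rate)
            for ch in range(trial.n_channels)
        ])
        assert mf_last / mf_first == pytest.approx(0.90, abs=0.03)

    def test_seed_determinism(self):
        gt = small_truth()
        cfg = SimConfig(n_muscles=4, n_synergies=2, fatigue_duration=30.0, seed=1)
        a = simulate_fatiguing_trial(gt, 1, cfg)
        b = simulate_fatiguing_trial(gt, 1, cfg)
        assert np.array_equal(a.signal, b.signal)


class TestGroundTruthValidation:
    def test_rejects_negative_weights(self):
        w = np.array([[1.0, -0.1], [0.2, 1.0], [0.1, 0.5]])
        with pytest.raises(ValueError):
            GroundTruth(
                weights=w / np.linalg.norm(w, axis=0),
                preferred_directions=np.eye(3)[:2],
                tuning_gain=[1, 1], fatigue_decay=[0.8, 0.8],
            )

    def test_rejects_out_of_range_fractions(self):
        gt = small_truth()
        with pytest.raises(ValueError):
            GroundTruth(
                weights=gt.weights,
                preferred_directions=gt.preferred_directions,
                tuning_gain=gt.tuning_gain,
                fatigue_decay=[0.8, 1.5],
            )
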