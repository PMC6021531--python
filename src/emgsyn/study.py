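"""End-to-end study pipelines on synthetic sessions.

These convenience drivers chain the pipeline stages the way the study design
intends: a multidirectional session is reduced to one envelope vector per
direction, factorized with VAF order selection and tuned; a set of fatiguing
trials (one per synergy, held in its preferred direction) is epoched,
factorized per epoch, and scored for structure conservation (scalar products
vs the shuffled null, fixed-W cross-validation) and fatigue metrics.

Analysis envelopes here skip the per-channel unit-variance step: that step
rescales the rows of W and therefore changes the basis in which synergies
are expressed, which would make comparisons against externally defined
(planted) weight vectors ill-posed.  Amplitude normalisation uses one shared
maximum over the whole concatenated session so relative muscle contributions
and tuning-curve shapes are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fatigue import FatigueMetrics, epoch_fatigue_metrics, normalize_to_epoch1
from .nmf import OrderSelection, SynergyNMF, SynergyNMFResults, fit_coefficients, match_synergies, select_order
from .preprocessing import EnvelopeConfig, epoch_fatiguing, trim_multidirectional
from .similarity import NullDistribution, cross_validate_fixed_w, shuffled_null
from .simulate import (
    GroundTruth,
    SimConfig,
    generate_direction_set,
    simulate_fatiguing_trial,
    simulate_multidirectional_session,
)
from .tuning import TuningResult, tuning_curve

__all__ = [
    "ANALYSIS_ENVELOPE",
    "MultidirectionalStudy",
    "FatigueStudy",
    "run_multidirectional_study",
    "run_fatigue_study",
]

#: Envelope settings for planted-truth analysis pipelines (see module docstring).
ANALYSIS_ENVELOPE = EnvelopeConfig(normalize="none", unit_variance=False)


@dataclass
class MultidirectionalStudy:
    """Reduced data and fitted synergies of one multidirectional session."""

    data: np.ndarray                 # (n_muscles, n_directions) envelope means
    directions: np.ndarray
    selection: OrderSelection
    results: SynergyNMFResults       # fit at the selected order
    tuning: TuningResult


def run_multidirectional_study(
    ground_truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
    k_range: range | None = None,
    directions: np.ndarray | None = None,
) -> MultidirectionalStudy:
    """Simulate and analyse one 26-direction target-matching session."""
    if directions is None:
        directions = generate_direction_set(26)
    cfg = replace(config, seed=seed if seed is not None else config.seed)
    trials = simulate_multidirectional_session(ground_truth, directions, cfg)
    cols = [trim_multidirectional(t, ANALYSIS_ENVELOPE) for t in trials]
    data = np.column_stack(cols)
    data = data / data.max()  # shared maximum over the concatenated session
    selection = select_order(data, k_range=k_range, seed=seed)
    results = selection.results_by_k[selection.order]
    tun = tuning_curve(results.coefficients, directions)
    return MultidirectionalStudy(
        data=data, directions=directions, selection=selection,
        results=results, tuning=tun,
    )


@dataclass
class FatigueStudy:
    """Per-epoch synergies and fatigue scoring of a set of fatiguing trials.

    One fatiguing trial is simulated per planted synergy (held in that
    synergy's preferred direction).  Per epoch, the rebinned envelopes of
    all trials are concatenated before extraction so that every synergy is
    active in the data each epoch's factorization sees.
    """

    ground_truth: GroundTruth
    epoch_data: list[np.ndarray]            # per epoch: (muscles, 100 * n_trials)
    epoch_results: list[SynergyNMFResults]  # free NMF per epoch
    epoch_weights: np.ndarray               # (n_epochs, muscles, order), matched to epoch 1
    within_similarities: np.ndarray         # cross-epoch scalar products per synergy
    null: NullDistribution
    fixed_w_vaf: np.ndarray                 # epochs 2..n with epoch-1 W frozen
    activation_pct: np.ndarray              # (n_trials, n_epochs) target-synergy C, % of epoch 1
    metrics: list[FatigueMetrics]           # per trial

    @property
    def mean_fixed_w_vaf(self) -> float:
        return float(self.fixed_w_vaf.mean())

    def mean_mf_pct(self) -> np.ndarray:
        """Channel-averaged normalized median frequency per trial, (n_trials, n_epochs).

        All channels share the planted spectral compression, so averaging
        median frequency across the 14 muscles suppresses single-channel
        estimation noise.
        """
        return np.array([m.mf_normalized.mean(axis=0) for m in self.metrics])

    def dominant_mf_pct(self) -> np.ndarray:
        """Normalized MF of each trial's dominant (highest-weight) muscle."""
        out = []
        for r, m in enumerate(self.metrics):
            ch = int(np.argmax(self.ground_truth.weights[:, r]))
            out.append(m.mf_normalized[ch])
        return np.array(out)


def run_fatigue_study(
    ground_truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
    order: int | None = None,
    n_shuffles: int = 1000,
) -> FatigueStudy:
    """Simulate and analyse one fatiguing trial per synergy.

    Pipeline: per-trial envelope extraction and five-epoch rebinning; per
    epoch, free NMF on the concatenated envelopes of all trials; Hungarian
    matching of later epochs' synergies to epoch 1; cross-epoch scalar
    products judged against the shuffled null (95th percentile of 1000
    global shuffles of pooled weight values); fixed-W cross-validation of
    epochs 2..5 with the epoch-1 structure frozen; per-epoch activation
    coefficients from fixed-W fits (scale-consistent across epochs),
    normalized to epoch 1; Welch median-frequency and RMS fatigue metrics
    per trial.
    """
    k = order if order is not None else ground_truth.n_synergies
    base = 0 if seed is None else seed
    cfg = replace(config, seed=seed if seed is not None else config.seed)
    n_trials = ground_truth.n_synergies

    epoched = []
    for r in range(n_trials):
        trial = simulate_fatiguing_trial(ground_truth, r, cfg)
        epoched.append(epoch_fatiguing(trial, ANALYSIS_ENVELOPE))
    n_epochs = epoched[0].n_epochs

    epoch_data = [
        np.hstack([ep.envelopes[e].T for ep in epoched]) for e in range(n_epochs)
    ]
    epoch_results = [
        SynergyNMF(D, k).fit(seed=base + e) for e, D in enumerate(epoch_data)
    ]

    W1 = epoch_results[0].weights
    matched = np.empty((n_epochs, W1.shape[0], k))
    for e, res in enumerate(epoch_results):
        perm, _ = match_synergies(res.weights, W1)
        matched[e] = res.weights[:, perm]
    sims = [
        float(matched[a, :, j] @ matched[b, :, j])
        for j in range(k)
        for a in range(n_epochs)
        for b in range(a + 1, n_epochs)
    ]

    pool = np.vstack([res.weights.T for res in epoch_results])
    null = shuffled_null(pool, n_shuffles=n_shuffles, seed=seed)

    fixed_vaf = cross_validate_fixed_w(W1, epoch_data[1:], seed=base)

    # Activation trajectories: C refitted with W1 frozen (scale-consistent);
    # trial r occupies columns [100 r, 100 (r + 1)) of each epoch's data.
    n_bins = epoched[0].envelopes[0].shape[0]
    perm_gt, _ = match_synergies(W1, ground_truth.weights)
    target_means = np.empty((n_trials, n_epochs))
    for e, D in enumerate(epoch_data):
        C = fit_coefficients(W1, D, seed=base + 7 * e)
        for r in range(n_trials):
            seg = C[:, r * n_bins:(r + 1) * n_bins]
            target_means[r, e] = seg[perm_gt[r]].mean()
    activation_pct = normalize_to_epoch1(target_means)

    metrics = [epoch_fatigue_metrics(ep) for ep in epoched]
    return FatigueStudy(
        ground_truth=ground_truth,
        epoch_data=epoch_data,
        epoch_results=epoch_results,
        epoch_weights=matched,
        within_similarities=np.array(sims),
        null=null,
        fixed_w_vaf=fixed_vaf,
        activation_pct=activation_pct,
        metrics=metrics,
    )
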