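# Methods

This note documents the models, numerical choices and limitations behind
`emgsyn`, in the order the pipeline runs.

## Synthetic EMG generator

**Signal model.** Each channel is an amplitude-modulated band-limited
Gaussian carrier plus additive white noise:

```
x_m(t) = e_m(t) · c_m(t) + n_m(t),        e(t) = W · a(t)
```

`W` (muscles × synergies, non-negative, unit-norm columns) is the planted
synergy structure; `a(t)` the planted activation coefficients.  Carriers are
independent per channel, built by FFT masking of white Gaussian noise to the
20–200 Hz band and scaled so `E|c| = 1`; the rectified signal mean then
equals the planted envelope, which is what makes every downstream stage
verifiable by parameter recovery.  A surface-EMG interference pattern is
well approximated by band-limited Gaussian noise at moderate-to-high
contraction levels; we adopt it because it gives a controllable,
analytically known spectrum.  The generator does **not** model motor-unit
recruitment or firing statistics, electrode artefacts, ECG contamination or
cross-talk — passing tests therefore demonstrate correctness of the
analysis chain on the assumed signal model, not robustness to every
real-data pathology.

**Directional tuning.** Activation follows a rectified cosine,
`a_r(d) = g_r · max(0, d · PD_r)`: the simplest law consistent with
activation peaking at a preferred direction and decaying monotonically with
angle.  The true tuning width of human synergies is not quantitatively
established; the cosine choice is an assumption.  A useful property of the
26-direction lattice set (closed under negation, `Σ QQᵀ = (26/3) I`) is
that the activation-weighted-mean PD estimator is exactly aligned with the
planted PD under this law, so angular recovery error reflects noise alone.

**Fatigue trajectories.** During a fatiguing trial held in synergy r's
preferred direction, every synergy's activation declines linearly from its
tuned initial value to `fatigue_decay` times it (default 0.755, i.e. a
24.5% terminal decrease), and the carrier spectrum compresses linearly in
time by `spectral_compression` (default 0.9).  Linear trajectories make the
planted epoch values analytic: with epochs centred at 2.5/25/50/75/97.5% of
the trial, the epoch-V/epoch-I activation ratio is
`(1 − 0.245·0.975)/(1 − 0.245·0.025) ≈ 76.6%` and the median-frequency
ratio `≈ 90.5%`.  Spectral compression is realised by time-warping a
stationary carrier, `y(t) = c(τ(t))` with `τ'(t)` the desired compression
factor, which scales the instantaneous spectrum without touching amplitude
statistics.  `W` is constant throughout: structure conservation is the
planted truth.

**Noise.** SNR is defined on the envelope scale: the ratio of modulated
signal power (averaged over channels and time) to additive white-noise
power, in dB (default 30).  A trial with no planted activation falls back
to a small absolute noise floor.  Because the white noise is broadband,
weakly active channels carry a slightly higher in-band noise fraction,
which biases their median frequency upward; at 30 dB this bias is ≲1.5%
on channel-averaged trajectories.

**Defaults as study conditions.** 14 muscles, 3 synergies, 2000 Hz, 26
directions, 4 s target-matching holds, 270 s fatiguing trials (the mean
time to task failure in comparable isometric protocols), 30 dB SNR.
Replicate-heavy tests use 120 s fatiguing trials; the planted per-epoch
ratios are duration-invariant, so this is purely a problem-size choice.

## Preprocessing

The envelope chain applies, in order: zero-phase 2nd-order Butterworth
band-pass 5–400 Hz; per-channel demeaning; full-wave rectification;
division of **all** channels by one shared maximum (preserving relative
muscle contributions — a per-channel maximum would destroy the weight
structure `W`); optional per-channel unit-variance scaling; zero-phase
2nd-order Butterworth 5 Hz low-pass; clipping of low-pass ringing at zero
(required for NMF; the clipped mass is below the filter ripple).
Zero-phase (forward–backward) filtering doubles the effective order but
avoids group delay, so envelope features stay aligned with the raw signal.

Two deliberate deviations of the *analysis pipelines* from the full chain:

1. **Unit variance is disabled** (`ANALYSIS_ENVELOPE`).  Scaling each
   channel to unit variance multiplies the rows of `W` by unknown
   per-channel factors — synergies are then expressed in a different basis,
   and comparing extracted weights against externally defined (planted)
   vectors becomes ill-posed.  The conventional chain (with unit variance)
   remains the default of `envelope_chain` for use on real data, where only
   internal consistency matters.
2. **The shared maximum is taken over the concatenated session**, not per
   direction: per-trial rescaling would distort tuning-curve shapes and
   bias preferred-direction estimates.

Fatiguing trials are analysed in five epochs of 5% of trial length starting
at 0, 23.75, 47.5, 71.25 and 95% of trial time — the first epoch uses the
very start and the last the very end, matching first-vs-last fatigue
comparisons — and each epoch envelope is rebinned to 100 points by block
means (leftover samples distributed one per bin from the first bin; the
rebinned mean equals the sample mean exactly when the counts divide).

## Synergy extraction

`SynergyNMF` minimises `‖D − WC‖²_F` by the classical multiplicative
updates with an epsilon guard (1e-12) in the denominators.  The error is
non-increasing at every iteration (asserted throughout the test suite).
Convergence: 20 consecutive iterations each changing the squared error by
less than 1e-4 relative; 10 uniform-random restarts, lowest error kept;
scale indeterminacy resolved by unit-normalising `W` columns into `C`;
permutation indeterminacy resolved by Hungarian assignment on scalar
products wherever factors are compared.

Model order is the smallest k whose fit reaches global VAF ≥ 0.90 with all
per-muscle local VAFs ≥ 0.80, with `VAF = 1 − Σ residual²/Σ data²`
(uncentred, computed globally and per row).  An alternative literal reading
— one minus the squared difference of data and reconstruction *variances*
over the squared data variance — is available via `vaf(..., method=
"variance")` but is insensitive to structural mismatch and not used for
selection.  Channels with zero energy get local VAF `NaN` rather than an
error so that structurally silent channels (possible in cross-validation)
do not abort a batch.

**Known limitation.** On exactly factorizable data built from *highly
collinear* non-negative factors (column cosines ≳ 0.75, typical of dense
uniform-random factors), multiplicative updates can stall in non-global
stationary points regardless of restart strategy, while coordinate-descent
solvers reach machine precision.  Synergy-like factors with distinct muscle
support (column cosines ≲ 0.3) are recovered to ~1e-12 relative error.
Fixed-coefficient fitting (`fit_coefficients`) reuses the same C-update and
convergence rule with `W` frozen; its VAF can never exceed the free fit of
the same order.

## Clustering and structure similarity

K-medoids runs PAM-style under cosine distance: alternate
assignment/medoid-update until stable, then a best-improvement swap phase
(any medoid against any non-medoid), best of 20 restarts.  On instances
with ≤ 8 points the solution matches the exhaustive optimum over all
medoid subsets.  The cluster count maximises the mean silhouette over
k = 2..min(8, n−1) — synergy counts in this literature are small.  Cluster
means are arithmetic means of member vectors, re-normalised.  The
cross-epoch "sorting" step pools all epochs' mean synergies, reclusters
them, and reports per final cluster one member per epoch (ties broken by
scalar product to the cluster mean) with explicit gaps; the final cluster
count may be smaller than the per-epoch count when a synergy is absorbed
into others.

The shuffled null applies, per shuffle, one *global* permutation of all
pooled weight entries across both muscles and epochs — the most
structure-destroying reading of shuffling "across epochs and muscles" —
then re-normalises each vector and collects all pairwise scalar products;
the conservation threshold is the 95th percentile of 1000 shuffles.
Because non-negative unit vectors have strictly positive expected overlap,
this chance level is high (~0.7 for 14 muscles), which is exactly why a
null distribution is needed rather than a fixed cut-off.

Per-epoch synergies of the fatiguing task are extracted from the
**concatenated** envelopes of all fatiguing trials: a single trial held in
one preferred direction leaves off-target synergies inactive (the
rectified-cosine law zeroes them beyond 90°), and weights fitted to an
inactive synergy are noise.

## Fatigue metrics

Median frequency uses the Welch PSD (Hann window, 1 s segments, 50%
overlap — unremarkable defaults, configurable) with linear interpolation
between frequency bins; RMS is computed on demeaned segments.  Both are
computed on band-pass-filtered (5–400 Hz) raw epoch segments, not on
envelopes, whose 5 Hz low-pass destroys spectral content.  All metrics are
normalised to epoch I (= 100%).  Single-channel Welch MF on a 13.5 s epoch
has ~3 Hz standard error — comparable to the planted per-epoch decrement —
so study-level trajectories average MF across channels (all channels share
the compression); per-channel values remain available, as does a
highest-weight ("dominant muscle") selector per synergy.

## Statistics

The one-way repeated-measures ANOVA computes the standard within-subject
sums-of-squares decomposition; Mauchly's W from the eigenvalues of the
orthonormal-contrast covariance with the usual first-order chi-square
approximation; Greenhouse–Geisser ε = (Σλ)²/((p−1)Σλ²); when Mauchly's
p < 0.05 both degrees of freedom are multiplied by ε (GG, not Huynh–Feldt).
The effect size is the within-subjects omega-squared
`(SS_effect − df·MS_error)/(SS_total + MS_subjects)`; omega-squared variants
differ across texts, so it is validated against its own closed form only.
F, W and ε match pingouin to ~1e-12 on fixed fixtures; pingouin's Mauchly
*p* uses a higher-order Box approximation and agrees to ~0.02.  A
zero-effect design (identical level means) reports F = 0, p = 1 even when
the error stratum is degenerate.  Paired comparisons use paired t-tests
with Bonferroni multiplication capped at 1; all-zero difference vectors
give t = 0, while constant non-zero differences are an error (no valid
denominator).  The similarity-vs-null comparison pairs within-cluster
scalar products with an equal-size sample of the null and reports t, p and
η² = t²/(t² + df).

## Problem sizes

Tests and the acceptance script run at the full study conditions (14
channels, 2000 Hz, 26 directions, 270 s fatigue trials) for single-run
checks, and use 10–20 seeded replicates with 120 s trials for rate-based
checks; these sizes are stated here as the package's reproducibility
conditions.
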