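# emgsyn

Muscle-synergy extraction and EMG fatigue analysis for multichannel surface
EMG, with a synthetic-signal generator that plants known synergy structure so
every stage of the pipeline can be validated by parameter recovery.

## The scientific problem

Time-invariant muscle synergies model the coordination of many muscles as a
small set of fixed weight patterns driven by shared time-varying commands:

```
D ≈ W · C
```

where `D` (muscles × samples) is the non-negative EMG envelope matrix, `W`
(muscles × synergies) the synergy structure, and `C` (synergies × samples)
the activation coefficients.  A central question in motor control is whether
`W` is a stable building block of movement — in particular, whether it
survives muscle fatigue, or whether the nervous system adapts by changing
only the recruitment `C`.  Answering it requires a full pipeline: envelope
preprocessing, non-negative matrix factorization with model-order selection,
directional tuning of synergies, clustering across participants and epochs,
structure-similarity testing against chance, and classical EMG fatigue
metrics.  `emgsyn` implements that pipeline and a generator of synthetic EMG
with planted ground truth (weights, preferred directions, fatigue
trajectories), so each stage can be tested for correct recovery.

## What is implemented

- **Synthetic EMG** (`emgsyn.simulate`): amplitude-modulated band-limited
  (20–200 Hz) Gaussian carriers at 2000 Hz over 14 channels.  Envelope
  expectation is `W · c(d)` with rectified-cosine directional tuning
  `c_r(d) = g_r · max(0, d · PD_r)` over the 26 target directions of the
  {-1,0,1}³ lattice.  Fatiguing trials hold a synergy's preferred direction
  with linearly declining activation and a linearly compressing spectrum
  (time-warped carrier), `W` constant throughout.
- **Preprocessing** (`emgsyn.preprocessing`): zero-phase 2nd-order
  Butterworth band-pass (5–400 Hz), demeaning, full-wave rectification,
  shared-maximum amplitude normalisation, optional per-channel unit-variance
  scaling, 5 Hz zero-phase low-pass; central-2 s trial averaging; five
  5%-length epochs every 25% of trial time, rebinned to 100 points.
- **Synergy extraction** (`emgsyn.nmf`): `SynergyNMF(data, order).fit(seed)`
  — multiplicative-update NMF (squared Frobenius loss, non-increasing error,
  convergence after 20 consecutive iterations changing the error by <0.01%,
  best of 10 random restarts, unit-norm `W` columns).  Model order is the
  smallest k with global VAF ≥ 90% and every muscle's local VAF ≥ 80%,
  where `VAF = 1 − ‖D − WC‖²_F / ‖D‖²_F` (globally and per muscle row).
- **Directional tuning** (`emgsyn.tuning`): preferred direction
  `PD_r = (1/T) Σ_i Q_i C_ri` and activation-by-direction tuning curves.
- **Clustering** (`emgsyn.cluster`): PAM-style K-medoids under cosine
  distance with a swap phase and 20 restarts, silhouette-based selection of
  the cluster count, and a second "sorting" clustering that matches mean
  synergies across epochs.
- **Structure conservation** (`emgsyn.similarity`): scalar products between
  unit weight vectors judged against the 95th percentile of a shuffled-
  synergy null (global permutation of pooled weight values, 1000 shuffles),
  and cross-validation with the epoch-1 `W` frozen while refitting `C`.
- **Fatigue metrics** (`emgsyn.fatigue`): Welch median frequency (Hann, 1 s
  segments, 50% overlap, interpolated) and RMS amplitude per epoch,
  normalised to the first epoch.
- **Statistics** (`emgsyn.stats`): one-way repeated-measures ANOVA with
  Mauchly's sphericity test and Greenhouse–Geisser correction, Bonferroni
  paired t-tests, Pearson correlations, and the paired t-test of
  within-cluster similarity against the shuffled null.

## Worked example

Simulate one 26-direction session at 30 dB SNR, select the synergy count,
and compare against the planted truth:

```python
import numpy as np
from emgsyn import (SimConfig, default_ground_truth,
                    run_multidirectional_study, match_synergies)

gt = default_ground_truth()
study = run_multidirectional_study(gt, SimConfig(), seed=42, k_range=range(1, 7))
print(study.selection.curve.to_string(index=False))
print(study.results.summary())
perm, sims = match_synergies(study.results.weights, gt.weights)
print("planted-W match:", np.round(sims, 3))
```

prints

```
 order  global_vaf  min_local_vaf
     1    0.679097       0.549413
     2    0.858003       0.626982
     3    0.999796       0.999297
     4    0.999829       0.999298
     5    0.999871       0.999662
     6    0.999906       0.999718

Muscle synergy NMF results
==========================
muscles: 14   samples: 26
order (synergies): 3
converged: True   iterations: 89
global VAF: 0.9998
min local VAF: 0.9993
...
planted-W match: [1. 1. 1.]
```

One synergy (k = 1) explains 68% of the data's energy; the planted order 3
is the first to clear both VAF thresholds (99.98% global), and the
recovered weight columns are essentially identical to the planted ones
(scalar products 1.000 after best assignment).  The estimated preferred
directions land within ~2° of the planted ones.

The fatigue side is driven the same way:

```python
from emgsyn import run_fatigue_study
fat = run_fatigue_study(gt, SimConfig(), seed=11)
print(fat.mean_fixed_w_vaf)              # 0.99  (epoch-1 W explains later epochs)
print(fat.within_similarities.min())     # 0.998 (> null threshold ~0.71)
print(fat.activation_pct[:, -1])         # ~76%  (planted decline to 75.5%)
print(fat.mean_mf_pct()[:, -1])          # ~91%  (planted spectral compression 0.9)
```

A thin CLI covers the shell workflow:
`emgsyn simulate --out session/ --seed 0` and
`emgsyn extract --in session/ --k-max 13 --seed 0`.

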