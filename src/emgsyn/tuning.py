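"""Directional tuning of muscle synergies.

Each synergy's preferred direction (PD) is the activation-weighted mean of
the trial direction vectors: ``PD_r = (1/T) * sum_i Q_i * C_ri`` where
``Q_i`` is the unit direction of trial i, ``C_ri`` the activation coefficient
of synergy r on that trial and T the number of trials.  On a direction set
that is symmetric under negation this estimator is unbiased for a
rectified-cosine tuning law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["SynergyTuning", "TuningResult", "preferred_direction", "tuning_curve"]


@dataclass
class SynergyTuning:
    """Tuning of a single synergy over the task directions."""

    raw_pd: np.ndarray          # activation-weighted mean direction (unnormalized)
    unit_pd: np.ndarray | None  # None when the raw PD is (numerically) zero
    defined: bool
    activations: np.ndarray
    directions: np.ndarray
    tuning_depth: float
    cosine_spearman: float | None = None

    def angle_to(self, direction: np.ndarray) -> float:
        """Angle in degrees between this synergy's PD and ``direction``."""
        if not self.defined:
            raise ValueError("preferred direction is undefined for this synergy")
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return float(np.degrees(np.arccos(np.clip(self.unit_pd @ d, -1.0, 1.0))))


@dataclass
class TuningResult:
    """Per-synergy tuning table and preferred directions."""

    synergies: list[SynergyTuning]

    def table(self) -> pd.DataFrame:
        rows = []
        for r, s in enumerate(self.synergies):
            for q, a in zip(s.directions, s.activations):
                rows.append(
                    {
                        "synergy": r,
                        "dir_x": q[0], "dir_y": q[1], "dir_z": q[2],
                        "activation": a,
                        "angle_to_pd": s.angle_to(q) if s.defined else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def preferred_direction(
    activations: np.ndarray, directions: np.ndarray
) -> SynergyTuning:
    """Estimate one synergy's PD as the activation-weighted mean direction.

    ``raw_pd = (1/T) * sum_i Q_i * C_i``; the unit PD is its normalisation.
    An (numerically) zero raw vector — e.g. isotropic activation over a
    negation-symmetric direction set — is flagged as undefined rather than
    silently normalized.
    """
    activations = np.asarray(activations, dtype=float).ravel()
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise ValueError("directions must be (n_trials, 3)")
    if len(activations) != len(directions):
        raise ValueError("activations and directions must have equal counts")
    if not np.allclose(np.linalg.norm(directions, axis=1), 1.0, atol=1e-6):
        raise ValueError("directions must be unit vectors")
    raw = directions.T @ activations / len(activations)
    scale = max(float(np.abs(activations).max()), 1e-300)
    defined = np.linalg.norm(raw) > 1e-9 * scale
    unit = raw / np.linalg.norm(raw) if defined else None
    amax = activations.max()
    depth = float((amax - activations.min()) / amax) if amax > 0 else 0.0
    return SynergyTuning(
        raw_pd=raw, unit_pd=unit, defined=defined,
        activations=activations, directions=directions, tuning_depth=depth,
    )


def tuning_curve(coefficients: np.ndarray, directions: np.ndarray) -> TuningResult:
    """Tuning curves and PDs for all synergies of a multidirectional session.

    Parameters
    ----------
    coefficients : ndarray, (n_synergies, n_trials)
        One trial-averaged activation coefficient per synergy per trial.
    directions : ndarray, (n_trials, 3)

    Each synergy also gets a monotonicity summary: the Spearman correlation
    between its activation and the cosine of the angle to its PD.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    out = []
    for row in coefficients:
        s = preferred_direction(row, directions)
        if s.defined and len(row) >= 3 and np.ptp(row) > 0:
            cosines = directions @ s.unit_pd
            rho = spearmanr(cosines, row).statistic
            s.cosine_spearman = float(rho)
        out.append(s)
    return TuningResult(synergies=out)
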