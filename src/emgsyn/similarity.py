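"""Synergy-structure conservation: scalar products, shuffled null, fixed-W CV.

Structure conservation across fatigue epochs is quantified two ways:

* scalar products between unit-normalized synergy weight vectors, judged
  against the 95th percentile of a null distribution built by globally
  shuffling weight values across muscles and epochs (destroying both muscle
  identity and synergy membership) and re-normalizing;
* cross-validation in which the weight matrix W extracted from the first
  epoch is held fixed and only activation coefficients are refitted to the
  later epochs' envelopes, scoring each epoch by global VAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import default_rng

from .nmf import fit_coefficients, vaf

__all__ = ["NullDistribution", "similarity", "shuffled_null", "cross_validate_fixed_w"]


def similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Scalar product of two unit-normalized synergy weight vectors."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    for w in (w1, w2):
        if abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise ValueError("weight vectors must be unit-normalized")
    return float(w1 @ w2)


@dataclass
class NullDistribution:
    """By-chance scalar-product distribution from shuffled synergies."""

    scalar_products: np.ndarray
    threshold: float  # 95th percentile
    n_shuffles: int
    seed: int | None

    def exceeds(self, value: float) -> bool:
        return value > self.threshold


def shuffled_null(
    weight_pool: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | None = None,
    percentile: float = 95.0,
) -> NullDistribution:
    """Null similarity distribution from unstructured (shuffled) synergies.

    Each shuffle applies one global permutation to all pooled weight entries
    (across both the muscle axis and the synergy/epoch axis), re-normalizes
    each shuffled vector, and records all pairwise scalar products.

    Parameters
    ----------
    weight_pool : ndarray, (n_vectors, n_muscles)
        All synergy weight vectors pooled across epochs/participants.
    """
    pool = np.asarray(weight_pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] < 2:
        raise ValueError("weight_pool must hold at least 2 weight vectors")
    if np.ptp(pool) == 0:
        raise ValueError("degenerate pool: all weight values identical")
    rng = default_rng(seed)
    n_vec, n_mus = pool.shape
    flat = pool.ravel()
    iu = np.triu_indices(n_vec, k=1)
    samples = []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(flat).reshape(n_vec, n_mus)
        norms = np.linalg.norm(shuffled, axis=1)
        ok = norms > 0
        U = shuffled[ok] / norms[ok, None]
        if U.shape[0] < 2:
            continue
        sims = U @ U.T
        k = U.shape[0]
        samples.append(sims[np.triu_indices(k, k=1)])
    products = np.concatenate(samples)
    return NullDistribution(
        scalar_products=products,
        threshold=float(np.percentile(products, percentile)),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def cross_validate_fixed_w(
    w_epoch1: np.ndarray,
    epochs: list[np.ndarray],
    seed: int | None = None,
    **fit_kwargs,
) -> np.ndarray:
    """Global VAF of later epochs reconstructed with epoch-1 structure frozen.

    For each epoch envelope matrix (muscles x samples), activation
    coefficients are fitted by multiplicative updates with W fixed, and the
    global VAF of ``W @ C`` against that epoch's data is returned.
    """
    W = np.asarray(w_epoch1, dtype=float)
    out = []
    for i, data in enumerate(epochs):
        data = np.asarray(data, dtype=float)
        if data.shape[0] != W.shape[0]:
            raise ValueError("epoch data disagrees with W on the muscle dimension")
        C = fit_coefficients(W, data, seed=None if seed is None else seed + i,
                             **fit_kwargs)
        out.append(vaf(data, W @ C).global_vaf)
    return np.array(out)
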