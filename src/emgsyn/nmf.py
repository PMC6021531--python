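"""Muscle-synergy extraction by non-negative matrix factorization.

The factorization model is ``D ~ W @ C`` where ``D`` (muscles x samples) is
the non-negative EMG envelope matrix, ``W`` (muscles x synergies) the synergy
structure and ``C`` (synergies x samples) the activation coefficients.  W and
C are fitted by the classical multiplicative update rule for the squared
Frobenius loss, whose reconstruction error is non-increasing at every
iteration.  Convergence is declared when 20 consecutive iterations each
change the error by less than 0.01% (relative); the best of several random
restarts is kept.  After fitting, W columns are scaled to unit Euclidean
norm with the inverse scale absorbed into C, resolving the scale
indeterminacy of NMF.

Model order (the number of synergies) is selected with dual
variance-accounted-for (VAF) criteria: the smallest order whose
reconstruction reaches a global VAF of at least 90% while every individual
muscle reaches a local VAF of at least 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SynergyNMF",
    "SynergyNMFResults",
    "VAFResult",
    "OrderSelection",
    "nmf_fit",
    "fit_coefficients",
    "vaf",
    "select_order",
    "match_synergies",
]

_EPS = 1e-12


@dataclass
class VAFResult:
    """Variance accounted for by a reconstruction.

    ``global_vaf`` is computed on the whole matrix, ``local_vaf`` per muscle
    (row).  Values are at most 1 and may be negative when the reconstruction
    is worse than predicting zero.
    """

    global_vaf: float
    local_vaf: np.ndarray
    order: int | None = None


def vaf(
    data: np.ndarray,
    reconstruction: np.ndarray,
    order: int | None = None,
    method: str = "residual",
) -> VAFResult:
    """Global and per-muscle VAF of a reconstruction.

    Parameters
    ----------
    method : {"residual", "variance"}
        ``"residual"`` (default) is the conventional uncentred form
        ``1 - ||D - R||^2 / ||D||^2``, applied globally and per row.
        ``"variance"`` is the literal squared-difference-of-variances
        reading ``1 - (var(D) - var(R))^2 / var(D)^2``, provided as a
        documented alternative; it is insensitive to structural mismatch
        and not recommended.
    """
    data = np.asarray(data, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if data.shape != reconstruction.shape:
        raise ValueError("data and reconstruction must have matching shapes")
    if method == "residual":
        denom = np.sum(data**2)
        if denom <= 0:
            raise ValueError("degenerate input: data has zero energy")
        resid = data - reconstruction
        g = 1.0 - np.sum(resid**2) / denom
        row_denom = np.sum(data**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            local = 1.0 - np.sum(resid**2, axis=1) / row_denom
        local[row_denom <= 0] = np.nan  # silent channel: local VAF undefined
    elif method == "variance":
        vd, vr = np.var(data), np.var(reconstruction)
        if vd <= 0:
            raise ValueError("degenerate input: data has zero variance")
        g = 1.0 - (vd - vr) ** 2 / vd**2
        vdr = np.var(data, axis=1)
        if np.any(vdr <= 0):
            raise ValueError("degenerate input: a channel has zero variance")
        local = 1.0 - (vdr - np.var(reconstruction, axis=1)) ** 2 / vdr**2
    else:
        raise ValueError(f"unknown VAF method {method!r}")
    return VAFResult(global_vaf=float(g), local_vaf=local, order=order)


def _mu_iterate(
    data: np.ndarray,
    W: np.ndarray,
    C: np.ndarray,
    max_iter: int,
    rel_tol: float,
    patience: int,
    update_w: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """Run multiplicative updates; returns (W, C, error history, converged, iters)."""
    err_prev = float(np.linalg.norm(data - W @ C) ** 2)
    history = [err_prev]
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C *= (W.T @ data) / (W.T @ W @ C + _EPS)
        if update_w:
            W *= (data @ C.T) / (W @ C @ C.T + _EPS)
        err = float(np.linalg.norm(data - W @ C) ** 2)
        history.append(err)
        rel = abs(err_prev - err) / (err_prev + _EPS)
        stable = stable + 1 if rel < rel_tol else 0
        err_prev = err
        if stable >= patience:
            converged = True
            break
    return W, C, history, converged, it


class SynergyNMF:
    """Synergy-extraction model for a non-negative envelope matrix.

    Parameters
    ----------
    data : ndarray, shape (n_muscles, n_samples)
        Non-negative envelope matrix D.
    order : int
        Number of synergies k, with ``1 <= k <= n_muscles - 1``.
    n_restarts : int
        Random restarts; the lowest-error solution is returned.
    max_iter : int
        Iteration cap per restart.
    rel_tol, patience : float, int
        Convergence rule: ``patience`` consecutive iterations must each
        change the squared reconstruction error by less than ``rel_tol``
        (relative).  The defaults implement the 20-iteration / 0.01% rule.

    Examples
    --------
    >>> model = SynergyNMF(envelopes, order=3)
    >>> res = model.fit(seed=0)
    >>> res.weights.shape
    (14, 3)
    """

    def __init__(
        self,
        data: np.ndarray,
        order: int,
        n_restarts: int = 10,
        max_iter: int = 5000,
        rel_tol: float = 1e-4,
        patience: int = 20,
    ) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (muscles x samples)")
        if np.any(data < 0):
            raise ValueError("NMF input must be non-negative")
        if not 1 <= order <= data.shape[0] - 1:
            raise ValueError(
                f"order must be in [1, {data.shape[0] - 1}], got {order}"
            )
        self.data = data
        self.order = int(order)
        self.n_restarts = int(n_restarts)
        self.max_iter = int(max_iter)
        self.rel_tol = float(rel_tol)
        self.patience = int(patience)

    def fit(self, seed: int | SeedSequence | None = None) -> "SynergyNMFResults":
        """Fit W and C by multiplicative updates, best of ``n_restarts``."""
        m, n = self.data.shape
        scale = np.sqrt(self.data.mean() / self.order + _EPS)
        ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
        best = None
        for child in ss.spawn(self.n_restarts):
            rng = default_rng(child)
            W = scale * rng.uniform(0.1, 1.0, size=(m, self.order))
            C = scale * rng.uniform(0.1, 1.0, size=(self.order, n))
            W, C, history, converged, iters = _mu_iterate(
                self.data, W, C, self.max_iter, self.rel_tol, self.patience
            )
            if best is None or history[-1] < best[2][-1]:
                best = (W, C, history, converged, iters)
        W, C, history, converged, iters = best
        W, C = _normalize_columns(W, C)
        return SynergyNMFResults(
            model=self, weights=W, coefficients=C,
            error_history=np.array(history), converged=converged, n_iter=iters,
        )


def _normalize_columns(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize W columns, absorbing the scales into C (W @ C unchanged)."""
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return W / norms, C * norms[:, None]


@dataclass
class SynergyNMFResults:
    """Fitted synergy structure and activation coefficients.

    Attributes
    ----------
    weights : ndarray, (n_muscles, order)
        Synergy structure W, columns unit-normalized.
    coefficients : ndarray, (order, n_samples)
        Activation coefficients C (scales absorbed from W).
    error_history : ndarray
        Squared Frobenius reconstruction error per iteration (best restart).
    converged : bool
    n_iter : int
    """

    model: SynergyNMF
    weights: np.ndarray
    coefficients: np.ndarray
    error_history: np.ndarray
    converged: bool
    n_iter: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.weights @ self.coefficients

    @property
    def order(self) -> int:
        return self.model.order

    def vaf(self, method: str = "residual") -> VAFResult:
        return vaf(self.model.data, self.reconstruction, self.order, method=method)

    def summary(self) -> str:
        v = self.vaf()
        lines = [
            "Muscle synergy NMF results",
            "==========================",
            f"muscles: {self.model.data.shape[0]}   samples: {self.model.data.shape[1]}",
            f"order (synergies): {self.order}",
            f"converged: {self.converged}   iterations: {self.n_iter}",
            f"global VAF: {v.global_vaf:.4f}",
            f"min local VAF: {v.local_vaf.min():.4f}",
            "",
            "Synergy weights (W):",
            pd.DataFrame(
                self.weights,
                columns=[f"S{r + 1}" for r in range(self.order)],
            ).round(3).to_string(),
        ]
        return "\n".join(lines)


def nmf_fit(
    data: np.ndarray,
    order: int,
    seed: int | None = None,
    max_iter: int = 5000,
    **kwargs,
) -> SynergyNMFResults:
    """Functional wrapper: fit ``SynergyNMF(data, order).fit(seed)``."""
    return SynergyNMF(data, order, max_iter=max_iter, **kwargs).fit(seed=seed)


def fit_coefficients(
    weights: np.ndarray,
    data: np.ndarray,
    seed: int | None = None,
    max_iter: int = 5000,
    rel_tol: float = 1e-4,
    patience: int = 20,
) -> np.ndarray:
    """Fit activation coefficients C with the synergy structure W frozen.

    Uses the same epsilon-guarded multiplicative C-update and convergence
    rule as the free factorization; only C is updated.
    """
    weights = np.asarray(weights, dtype=float)
    data = np.asarray(data, dtype=float)
    if weights.shape[0] != data.shape[0]:
        raise ValueError("weights and data disagree on the muscle dimension")
    if np.any(data < 0) or np.any(weights < 0):
        raise ValueError("NMF input must be non-negative")
    rng = default_rng(seed)
    scale = np.sqrt(data.mean() / weights.shape[1] + _EPS)
    C = scale * rng.uniform(0.1, 1.0, size=(weights.shape[1], data.shape[1]))
    _, C, _, _, _ = _mu_iterate(
        data, weights.copy(), C, max_iter, rel_tol, patience, update_w=False
    )
    return C


@dataclass
class OrderSelection:
    """Outcome of the VAF model-order sweep."""

    order: int
    vaf_by_k: list[VAFResult]
    results_by_k: dict[int, SynergyNMFResults] = field(default_factory=dict)
    satisfied: bool = True

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": [v.order for v in self.vaf_by_k],
                "global_vaf": [v.global_vaf for v in self.vaf_by_k],
                "min_local_vaf": [v.local_vaf.min() for v in self.vaf_by_k],
            }
        )


def select_order(
    data: np.ndarray,
    global_min: float = 0.90,
    local_min: float = 0.80,
    k_range: range | None = None,
    seed: int | None = None,
    **fit_kwargs,
) -> OrderSelection:
    """Select the number of synergies by the dual VAF criteria.

    Sweeps candidate orders and returns the smallest k whose best-restart fit
    reaches ``global_min`` global VAF with every muscle at or above
    ``local_min`` local VAF; if no candidate qualifies, the largest k is
    returned with ``satisfied=False``.
    """
    data = np.asarray(data, dtype=float)
    if k_range is None:
        k_range = range(1, data.shape[0])
    ss = SeedSequence(seed)
    children = ss.spawn(len(k_range))
    vaf_by_k: list[VAFResult] = []
    results: dict[int, SynergyNMFResults] = {}
    chosen = None
    for k, child in zip(k_range, children):
        res = SynergyNMF(data, k, **fit_kwargs).fit(seed=child)
        v = res.vaf()
        vaf_by_k.append(v)
        results[k] = res
        if chosen is None and v.global_vaf >= global_min and v.local_vaf.min() >= local_min:
            chosen = k
    if chosen is None:
        return OrderSelection(order=max(k_range), vaf_by_k=vaf_by_k,
                              results_by_k=results, satisfied=False)
    return OrderSelection(order=chosen, vaf_by_k=vaf_by_k,
                          results_by_k=results, satisfied=True)


def match_synergies(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best assignment of estimated synergy columns to reference columns.

    Resolves NMF's permutation indeterminacy by Hungarian assignment on the
    pairwise scalar-product matrix of unit-normalized columns.

    Returns
    -------
    perm : ndarray of int
        ``perm[j]`` is the estimated column matched to reference column j.
    similarities : ndarray
        Scalar product of each matched pair.
    """
    est = estimated / (np.linalg.norm(estimated, axis=0, keepdims=True) + _EPS)
    ref = reference / (np.linalg.norm(reference, axis=0, keepdims=True) + _EPS)
    sim = ref.T @ est  # (n_ref, n_est)
    row, col = linear_sum_assignment(-sim)
    perm = np.empty(len(row), dtype=int)
    perm[row] = col
    return perm, sim[row, col]
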