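"""Clustering of synergy weight vectors: K-medoids (PAM) under cosine distance.

Synergies pooled across participants are grouped per epoch, cluster counts
are chosen by the mean silhouette index, clusters are averaged into mean
synergy sets, and a second "sorting" clustering matches mean synergies
across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterResult",
    "MatchedSequences",
    "cosine_distance",
    "pairwise_cosine_distance",
    "kmedoids",
    "select_k",
    "sort_across_epochs",
]


def cosine_distance(w1: np.ndarray, w2: np.ndarray) -> float:
    """1 - cos(w1, w2); in [0, 1] for non-negative vectors."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - (w1 @ w2) / (n1 * n2))


def pairwise_cosine_distance(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine distance undefined for zero vectors")
    U = X / norms[:, None]
    D = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


@dataclass
class ClusterResult:
    labels: np.ndarray
    medoids: np.ndarray
    k: int
    total_distance: float
    mean_silhouette: float | None
    cluster_means: np.ndarray  # (k, n_features), unit-normalized

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    labels = np.argmin(sub, axis=1)
    return labels, float(sub[np.arange(D.shape[0]), labels].sum())


def _cluster_means(X: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    k = len(medoids)
    means = np.zeros((k, X.shape[1]))
    for c in range(k):
        members = X[labels == c]
        # a cluster can end up empty when duplicate points tie at zero distance
        m = members.mean(axis=0) if len(members) else X[medoids[c]]
        norm = np.linalg.norm(m)
        means[c] = m / norm if norm > 0 else m
    return means


def kmedoids(
    synergies: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> ClusterResult:
    """PAM-style K-medoids under cosine distance, best of ``n_restarts``.

    Alternates assignment of points to the nearest medoid with replacement of
    each cluster's medoid by the member minimizing the within-cluster total
    distance, until the medoid set stabilizes; a best-improvement swap phase
    (replace any medoid by any non-medoid while the objective drops) then
    polishes the solution.  The objective (total distance of points to their
    medoid) is non-increasing at every step.
    """
    X = np.asarray(synergies, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of synergies ({n})")
    D = pairwise_cosine_distance(X)
    ss = SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in ss.spawn(n_restarts):
        rng = default_rng(child)
        medoids = rng.choice(n, size=k, replace=False)
        labels, total = _assign(D, medoids)
        for _ in range(max_iter):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            new_labels, new_total = _assign(D, new_medoids)
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                labels, total = new_labels, new_total
                break
            medoids, labels, total = new_medoids, new_labels, new_total
        # PAM swap phase: try replacing each medoid by each non-medoid
        improved = True
        while improved:
            improved = False
            swap = None
            for ci in range(k):
                for h in range(n):
                    if h in medoids:
                        continue
                    cand = medoids.copy()
                    cand[ci] = h
                    _, cand_total = _assign(D, cand)
                    if cand_total < total - 1e-15:
                        total, swap = cand_total, cand
                        improved = True
            if swap is not None:
                medoids = swap
                labels, total = _assign(D, medoids)
        if best is None or total < best[2]:
            best = (labels.copy(), np.sort(medoids), total)
    labels, medoids, total = best
    sil = None
    if 2 <= k <= n - 1 and len(np.unique(labels)) >= 2:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return ClusterResult(
        labels=labels, medoids=medoids, k=k, total_distance=total,
        mean_silhouette=sil, cluster_means=_cluster_means(X, labels, medoids),
    )


def select_k(
    synergies: np.ndarray,
    k_range: range | None = None,
    seed: int | None = None,
    n_restarts: int = 20,
) -> tuple[int, dict[int, float]]:
    """Cluster count maximizing the mean silhouette index (cosine distance)."""
    X = np.asarray(synergies, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 synergies to select a cluster count")
    if k_range is None:
        k_range = range(2, min(8, n - 1) + 1)
    scores: dict[int, float] = {}
    for k in k_range:
        res = kmedoids(X, k, seed=None if seed is None else seed * 131 + k,
                       n_restarts=n_restarts)
        if res.mean_silhouette is not None:
            scores[k] = res.mean_silhouette
    if not scores:
        raise ValueError("silhouette undefined for every candidate k")
    best = max(scores, key=lambda k: scores[k])
    return best, scores


@dataclass
class MatchedSequences:
    """Cross-epoch matching of mean synergies.

    ``sequences[c]`` maps epoch index -> (index within that epoch's mean set,
    weight vector), with missing epochs absent (a gap).  ``k`` may be smaller
    than the per-epoch synergy count when a synergy is absorbed into others.
    """

    k: int
    sequences: list[dict[int, tuple[int, np.ndarray]]]
    cluster_means: np.ndarray
    labels: np.ndarray
    epochs: np.ndarray
    gaps: list[list[int]] = field(default_factory=list)

    def sequence_similarities(self, c: int) -> np.ndarray:
        """Scalar products of each epoch's member with the cluster mean."""
        mean = self.cluster_means[c]
        sims = []
        for _, (_, w) in sorted(self.sequences[c].items()):
            sims.append(float((w / np.linalg.norm(w)) @ mean))
        return np.array(sims)


def sort_across_epochs(
    mean_sets: list[np.ndarray],
    seed: int | None = None,
    k_range: range | None = None,
) -> MatchedSequences:
    """Match similar mean synergies across epochs (the "sorting" clustering).

    Pools all epochs' mean synergies, clusters them with the same
    K-medoids/silhouette machinery, and emits per final cluster the ordered
    sequence of that synergy across epochs.  When a cluster holds more than
    one member from the same epoch, the member with the highest scalar
    product to the cluster mean takes the slot; clusters lacking a member in
    some epoch are reported with gaps.
    """
    if len(mean_sets) < 2:
        raise ValueError("need mean synergy sets from at least 2 epochs")
    pool = np.vstack(mean_sets)
    epochs = np.concatenate(
        [np.full(len(s), e, dtype=int) for e, s in enumerate(mean_sets)]
    )
    within = np.concatenate([np.arange(len(s)) for s in mean_sets])
    k, _ = select_k(pool, k_range=k_range, seed=seed)
    res = kmedoids(pool, k, seed=seed)
    sequences: list[dict[int, tuple[int, np.ndarray]]] = []
    gaps: list[list[int]] = []
    unit = pool / np.linalg.norm(pool, axis=1, keepdims=True)
    for c in range(k):
        members = res.members(c)
        seq: dict[int, tuple[int, np.ndarray]] = {}
        for e in range(len(mean_sets)):
            cands = members[epochs[members] == e]
            if cands.size == 0:
                continue
            sims = unit[cands] @ res.cluster_means[c]
            pick = cands[np.argmax(sims)]
            seq[e] = (int(within[pick]), pool[pick])
        sequences.append(seq)
        gaps.append([e for e in range(len(mean_sets)) if e not in seq])
    return MatchedSequences(
        k=k, sequences=sequences, cluster_means=res.cluster_means,
        labels=res.labels, epochs=epochs, gaps=gaps,
    )
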