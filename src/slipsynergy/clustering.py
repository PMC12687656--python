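"""Cross-participant clustering of muscle synergies into modes.

Unit-max synergy vectors from all participants of a stage are pooled and
grouped by k-means (squared Euclidean distance, many random restarts). The
number of clusters is the smallest k in 2..8 giving a local maximum of the
mean silhouette value. Cluster centroids ("modes") are named after their
dominant muscle (side prefix dropped when both sides of the same muscle
dominate within 5% of each other), ordered by the peak time of the mean
activation curve, and matched one-to-one across training stages by Pearson
correlation of the 8 weights; pairs with r above the critical value 0.83
(p < 0.01 at 6 degrees of freedom) count as the same mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_model import CANONICAL_LABELS
from . import stats as sstats
from .synergy import SynergySet

__all__ = [
    "PooledSynergies",
    "ClusteredModes",
    "ModeMatch",
    "pool",
    "kmeans",
    "select_k",
    "cluster_stage",
    "name_and_order",
    "match_stages",
    "compare_mode_weights",
]


@dataclass
class PooledSynergies:
    """Stage-level pool of unit-max synergy columns with provenance."""

    stage: str
    vectors: np.ndarray                 # [8 x n_pooled]
    labels: list[tuple[str, int]]       # (participant_id, synergy index)

    @property
    def n(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ClusteredModes:
    stage: str
    centroids: np.ndarray               # [8 x n_modes], unit-max columns
    assignments: np.ndarray             # pooled column -> mode index
    labels: list[tuple[str, int]]
    vectors: np.ndarray                 # [8 x n_pooled] member unit-max vectors
    silhouette_by_k: dict[int, float]
    chosen_k: int
    mode_names: list[str] = field(default_factory=list)
    mode_order: Optional[list[int]] = None          # by activation peak time
    mean_activations: Optional[np.ndarray] = None   # [n_modes x 100]
    inertia: float = np.nan

    def members(self, mode: int) -> list[tuple[str, int]]:
        return [lab for lab, a in zip(self.labels, self.assignments) if a == mode]


@dataclass
class ModeMatch:
    pairs: list[tuple[int, int, float]]     # (early mode, late mode, r)
    unmatched_early: list[int]
    unmatched_late: list[int]
    threshold: float

    def similarity_class(self, r: float) -> str:
        return "high" if r > self.threshold else "below_threshold"


def _unit_max_columns(w: np.ndarray) -> np.ndarray:
    col_max = w.max(axis=0)
    if np.any(col_max <= 0):
        raise ValueError("synergy column with non-positive maximum")
    return w / col_max


def pool(stage_synergies: Sequence[tuple[str, SynergySet]], stage: str = "") -> PooledSynergies:
    """Pool all participants' unit-max synergy vectors for one stage.

    ``stage_synergies`` pairs each participant id with their SynergySet.
    """
    if not stage_synergies:
        raise ValueError("no synergies to pool")
    cols, labels = [], []
    for pid, s in stage_synergies:
        w = _unit_max_columns(s.W)
        for j in range(s.k):
            cols.append(w[:, j])
            labels.append((pid, j))
    return PooledSynergies(stage=stage, vectors=np.column_stack(cols), labels=labels)


def kmeans(pooled: np.ndarray, k: int, n_init: int = 100, seed: int = 0
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` random-start k-means on synergy columns.

    Returns (assignments, centroids [8 x k], inertia). Deterministic given
    ``seed``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(pooled, dtype=float).T      # points in rows
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of pooled synergies {x.shape[0]}")
    km = KMeans(n_clusters=k, init="random", n_init=n_init,
                random_state=seed % (2 ** 32), algorithm="lloyd")
    assignments = km.fit_predict(x)
    return assignments, km.cluster_centers_.T, float(km.inertia_)


def select_k(pooled: np.ndarray, k_min: int = 1, k_max: int = 8,
             n_init: int = 100, seed: int = 0
             ) -> tuple[int, dict[int, float]]:
    """Smallest k whose mean silhouette is a local maximum.

    The nominal search range is 1..8, but the silhouette is undefined at
    k = 1, so the effective range is 2..min(8, n-1). Endpoints compare to
    their single neighbour.
    """
    x = np.asarray(pooled, dtype=float).T
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pooled synergies to select k")
    lo = max(2, k_min)
    hi = min(k_max, n - 1)
    sil: dict[int, float] = {}
    for k in range(lo, hi + 1):
        assignments, _, _ = kmeans(pooled, k, n_init=n_init, seed=seed)
        sil[k] = float(silhouette_score(x, assignments, metric="euclidean"))
    ks = sorted(sil)
    for k in ks:
        left = sil.get(k - 1, -np.inf)
        right = sil.get(k + 1, -np.inf)
        if sil[k] > left and sil[k] > right:
            return k, sil
    # flat plateaus: fall back to the global maximum (smallest k on ties)
    best = max(ks, key=lambda k: (sil[k], -k))
    return best, sil


def cluster_stage(pooled: PooledSynergies, k: Optional[int] = None,
                  k_min: int = 1, k_max: int = 8, n_init: int = 100,
                  seed: int = 0) -> ClusteredModes:
    """Cluster a stage's pooled synergies into modes.

    If ``k`` is None it is chosen by :func:`select_k`; passing ``k``
    explicitly supports sensitivity reruns (e.g. 5 vs 6 clusters).
    Centroids are recomputed as the arithmetic mean of member unit-max
    vectors, renormalized to unit max.
    """
    if k is None:
        k, sil = select_k(pooled.vectors, k_min, k_max, n_init=n_init, seed=seed)
    else:
        sil = {}
    assignments, _, inertia = kmeans(pooled.vectors, k, n_init=n_init, seed=seed)
    centroids = np.column_stack([
        pooled.vectors[:, assignments == j].mean(axis=1) for j in range(k)
    ])
    centroids = _unit_max_columns(centroids)
    return ClusteredModes(
        stage=pooled.stage, centroids=centroids, assignments=assignments,
        labels=pooled.labels, vectors=pooled.vectors,
        silhouette_by_k=sil, chosen_k=k, inertia=inertia,
    )


def name_and_order(modes: ClusteredModes, mean_activations: np.ndarray,
                   side_margin: float = 0.05) -> ClusteredModes:
    """Name modes by dominant muscle and order them by activation peak time.

    ``mean_activations`` is [n_modes x n_points], the mean time-normalized
    activation curve of each mode's members. The side prefix (R_/S_) is
    dropped when the same muscle on both sides dominates within
    ``side_margin`` of the top weight (e.g. W_TA).
    """
    k = modes.centroids.shape[1]
    if mean_activations.shape[0] != k:
        raise ValueError("one activation curve per mode required")
    names = []
    for j in range(k):
        w = modes.centroids[:, j]
        top = int(np.argmax(w))
        side, muscle = CANONICAL_LABELS[top].split("_")
        other = f"{'S' if side == 'R' else 'R'}_{muscle}"
        other_w = w[CANONICAL_LABELS.index(other)]
        if w[top] - other_w <= side_margin * w[top]:
            names.append(f"W_{muscle}")
        else:
            names.append(f"W_{side}_{muscle}")
    peak_times = np.argmax(mean_activations, axis=1)
    order = list(np.argsort(peak_times, kind="stable"))
    modes.mode_names = names
    modes.mode_order = order
    modes.mean_activations = mean_activations
    return modes


def match_stages(early: ClusteredModes, late: ClusteredModes,
                 threshold: float = 0.83) -> ModeMatch:
    """Greedy one-to-one matching of early vs late modes by Pearson r.

    All early x late centroid pairs are correlated over the 8 muscle
    weights; pairs are accepted in descending r until one side is
    exhausted. Pairs with r > ``threshold`` are classed as the same mode.
    """
    ne = early.centroids.shape[1]
    nl = late.centroids.shape[1]
    r = np.empty((ne, nl))
    for i in range(ne):
        for j in range(nl):
            r[i, j] = sstats.pearson_r(early.centroids[:, i], late.centroids[:, j]).statistic
    order = np.dstack(np.unravel_index(np.argsort(r, axis=None)[::-1], r.shape))[0]
    used_e, used_l, pairs = set(), set(), []
    for i, j in order:
        if i in used_e or j in used_l:
            continue
        pairs.append((int(i), int(j), float(r[i, j])))
        used_e.add(i)
        used_l.add(j)
        if len(pairs) == min(ne, nl):
            break
    return ModeMatch(
        pairs=pairs,
        unmatched_early=[i for i in range(ne) if i not in used_e],
        unmatched_late=[j for j in range(nl) if j not in used_l],
        threshold=threshold,
    )


def compare_mode_weights(early: ClusteredModes, late: ClusteredModes,
                         match: ModeMatch) -> dict[tuple[int, int], list]:
    """Paired t-test per muscle on member weights of each matched mode pair.

    Participants contributing to the mode in both stages are paired; a
    participant with two synergies in one mode has their weights averaged
    first. Modes present in only one stage are skipped with a warning.
    Returns {(early mode, late mode): [StatsResult per muscle]}.
    """
    def participant_means(modes: ClusteredModes, pooled_vectors: np.ndarray,
                          mode: int) -> dict[str, np.ndarray]:
        acc: dict[str, list[np.ndarray]] = {}
        for col, (lab, a) in enumerate(zip(modes.labels, modes.assignments)):
            if a == mode:
                acc.setdefault(lab[0], []).append(pooled_vectors[:, col])
        return {pid: np.mean(cols, axis=0) for pid, cols in acc.items()}

    results: dict[tuple[int, int], list] = {}
    for i, j, _r in match.pairs:
        em = participant_means(early, early.vectors, i)
        lm = participant_means(late, late.vectors, j)
        shared = sorted(set(em) & set(lm))
        if len(shared) < 3:
            warnings.warn(
                f"mode pair ({i},{j}) has only {len(shared)} paired participants; skipped"
            )
            continue
        e = np.array([em[p] for p in shared])     # [n_pairs x 8]
        l = np.array([lm[p] for p in shared])
        results[(i, j)] = [sstats.paired_t(e[:, mus], l[:, mus]) for mus in range(8)]
    for i in match.unmatched_early:
        warnings.warn(f"early mode {i} has no late-stage partner; skipped")
    for j in match.unmatched_late:
        warnings.warn(f"late mode {j} has no early-stage partner; skipped")
    return results
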