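"""Balanced undersampling of the majority (pseudo-hairpin) class.

The boosting trainer always fits a base learner on k positives and k
negatives, where k is the positive-class size.  The k negatives come from
two selectors:

* iteration 1 — K-means over all negatives (k clusters, Rogers-Tanimoto
  assignment in min-max-scaled space); the member closest to each cluster
  center is the representative, so the first balanced subset spans the
  negative class's structure;
* later iterations — weighted sampling without replacement, probability
  at each draw proportional to the remaining boosting weights, so the
  trainer concentrates on negatives the ensemble still misclassifies.

Both selectors are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .errors import InfeasibleSelectionError
from .similarity import rt_distance_matrix

_KMEANS_MAX_ITER = 100
_KMEANS_TOL = 1e-4


@dataclass(frozen=True)
class SelectionResult:
    indices: List[int]
    method: str  # "kmeans_representative" | "weight_proportional"
    seed: int

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise InfeasibleSelectionError("selected indices are not distinct")


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under the Rogers-Tanimoto distance."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d = rt_distance_matrix(X, np.asarray(centers)).min(axis=1)
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=probs)])
    return np.asarray(centers)


def select_initial_negatives(
    negatives: np.ndarray, k: int, seed: int
) -> SelectionResult:
    """Representative negatives via K-means in Rogers-Tanimoto space.

    ``negatives`` must already be scaled to nonnegative space (the trainer
    passes min-max-scaled features).  Lloyd iterations assign points to
    the nearest center under the Rogers-Tanimoto distance and recompute
    centers as arithmetic means; an emptied cluster is reseeded with the
    point farthest from its current center.  Each cluster contributes the
    member minimizing distance to its center.
    """
    X = np.asarray(negatives, dtype=float)
    n = X.shape[0]
    if k > n:
        raise InfeasibleSelectionError(f"k={k} exceeds {n} negatives")
    if k == n:
        return SelectionResult(list(range(n)), "kmeans_representative", seed)

    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(X, k, rng)
    prev_inertia = np.inf
    for _ in range(_KMEANS_MAX_ITER):
        dists = rt_distance_matrix(X, centers)
        assign = dists.argmin(axis=1)
        point_d = dists[np.arange(n), assign]
        for c in range(k):  # reseed empty clusters with the worst-fit point
            if not (assign == c).any():
                far = point_d.argmax()
                assign[far] = c
                centers[c] = X[far]
                point_d[far] = 0.0
        inertia = float(point_d.sum())
        new_centers = np.asarray(
            [X[assign == c].mean(axis=0) for c in range(k)]
        )
        if prev_inertia - inertia <= _KMEANS_TOL * max(prev_inertia, 1e-12):
            centers = new_centers
            break
        centers = new_centers
        prev_inertia = inertia

    dists = rt_distance_matrix(X, centers)
    assign = dists.argmin(axis=1)
    chosen: List[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in range(k):
        members = np.where((assign == c) & ~taken)[0]
        if members.size == 0:  # degenerate duplicates: fall back to any free point
            members = np.where(~taken)[0]
        best = members[dists[members, c].argmin()]
        chosen.append(int(best))
        taken[best] = True
    return SelectionResult(chosen, "kmeans_representative", seed)


def select_negatives_by_weight(
    weights: np.ndarray, k: int, seed: int
) -> SelectionResult:
    """Draw k distinct indices, each draw proportional to remaining weight.

    Implemented as an exponential race (draw E_i ~ Exp(1)/w_i and keep the
    k smallest), which is distributionally identical to sequential
    weighted draws without replacement and fully vectorized.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise InfeasibleSelectionError("negative weights are not allowed")
    positive = w > 0
    if positive.sum() < k:
        raise InfeasibleSelectionError(
            f"only {int(positive.sum())} positive-weight negatives for k={k}"
        )
    rng = np.random.default_rng(seed)
    keys = np.full(w.shape, np.inf)
    keys[positive] = rng.exponential(size=int(positive.sum())) / w[positive]
    order = np.argsort(keys, kind="stable")[:k]
    return SelectionResult([int(i) for i in order], "weight_proportional", seed)
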