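"""Multiple trajectory alignment (MTA) and model fitting.

Per-individual trajectories — short sequences of standardized seed-feature
vectors — are merged into consensus trajectories by analogy with multiple
sequence alignment: two sequences at a time are aligned with a dynamic
program (classic dynamic time warping: steps right/down/diagonal, no gap
penalty, since a trajectory is a continuous process where "gaps" are
repetitions rather than deletions), averaged along the optimal path, and the
running consensus is resampled to a fixed length before the next merge.

Because progressive merging depends on the order in which individuals are
folded in, the model keeps an *ensemble* of consensus trajectories, each
built from an independent random permutation of the individuals.  All
randomness flows from a single integer seed recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    DEFAULT_GRID_SIZE,
    IndividualTrajectory,
    LongitudinalDataset,
    StandardizationParams,
    build_trajectory,
    fit_standardization,
    validate_dataset,
)
from .seed import (
    DEFAULT_CONSISTENCY_MIN,
    DEFAULT_K,
    DEFAULT_RHO_MIN,
    SeedSet,
    seed_from_features,
    select_seed,
)

__all__ = [
    "AlignmentPath",
    "ConsensusTrajectory",
    "TrajectoryModel",
    "pairwise_align",
    "merge_along_path",
    "resample_consensus",
    "build_consensus",
    "fit",
]

DEFAULT_CONSENSUS_LENGTH = 50
DEFAULT_N_MEMBERS = 50
COST_METRICS = ("euclidean", "pearson")


@dataclass
class AlignmentPath:
    """Monotone warping path between two point-sequences.

    ``pairs`` holds 0-based ``(i, j)`` index pairs, starting at ``(0, 0)``
    and ending at ``(m-1, n-1)``; each step increments ``i``, ``j`` or both
    by exactly one.  ``total_cost`` is the sum of point costs along the path.
    """

    pairs: list[tuple[int, int]]
    total_cost: float


@dataclass
class ConsensusTrajectory:
    """Ordered consensus points (L x S) with per-point contribution weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights length mismatch")

    @property
    def length(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]


def _cost_matrix(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(A, B, metric="euclidean")
    if metric == "pearson":
        if A.shape[1] < 2:
            raise ValueError("pearson cost needs >= 2 features")
        return cdist(A, B, metric="correlation")  # 1 - r
    raise ValueError(f"unknown cost metric {metric!r}; choose from {COST_METRICS}")


def pairwise_align(
    A: np.ndarray, B: np.ndarray, cost_metric: str = "euclidean"
) -> AlignmentPath:
    """Optimal monotone alignment of two point-sequences (m x S vs n x S).

    Cumulative cost ``D[i, j] = d[i, j] + min(D[i-1, j], D[i-1, j-1],
    D[i, j-1])`` with out-of-range terms infinite; the returned path is a
    minimal-cost backtrace from ``(m-1, n-1)``.  Backtrace ties prefer the
    diagonal, then the step reducing ``i``, then the step reducing ``j``
    (determinism; favors compact consensus).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    d = _cost_matrix(A, B, cost_metric)
    m, n = d.shape
    D = np.full((m, n), np.inf)
    D[0, 0] = d[0, 0]
    for j in range(1, n):
        D[0, j] = d[0, j] + D[0, j - 1]
    for i in range(1, m):
        D[i, 0] = d[i, 0] + D[i - 1, 0]
        Dp = D[i - 1]
        Dc = D[i]
        dc = d[i]
        for j in range(1, n):
            Dc[j] = dc[j] + min(Dp[j - 1], Dp[j], Dc[j - 1])

    pairs = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            best = min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            if D[i - 1, j - 1] == best:
                i, j = i - 1, j - 1
            elif D[i - 1, j] == best:
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return AlignmentPath(pairs=pairs, total_cost=float(D[m - 1, n - 1]))


def merge_along_path(
    A: np.ndarray,
    B: np.ndarray,
    path: AlignmentPath,
    weights_A: np.ndarray | None = None,
    weights_B: np.ndarray | None = None,
) -> ConsensusTrajectory:
    """Average two aligned sequences point-by-point along a warping path.

    Each path step ``(i, j)`` yields one consensus point, the weighted mean
    ``(w_A[i] * A[i] + w_B[j] * B[j]) / (w_A[i] + w_B[j])`` with output
    weight ``w_A[i] + w_B[j]``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    wA = np.ones(A.shape[0]) if weights_A is None else np.asarray(weights_A, float)
    wB = np.ones(B.shape[0]) if weights_B is None else np.asarray(weights_B, float)
    ii = np.array([p[0] for p in path.pairs])
    jj = np.array([p[1] for p in path.pairs])
    wa = wA[ii]
    wb = wB[jj]
    points = (wa[:, None] * A[ii] + wb[:, None] * B[jj]) / (wa + wb)[:, None]
    return ConsensusTrajectory(points=points, weights=wa + wb)


def resample_consensus(c: ConsensusTrajectory, L_target: int) -> ConsensusTrajectory:
    """Resample a consensus to a fixed length along its (scaled) index axis.

    Points and weights are linearly interpolated onto ``L_target`` uniform
    positions; endpoints are preserved exactly.  Keeps the progressive merge
    from growing the path without bound.
    """
    if L_target < 3:
        raise ValueError("L_target must be >= 3")
    L = c.length
    if L < 2:
        raise ValueError("need >= 2 points to resample")
    if L_target == L:
        return ConsensusTrajectory(points=c.points.copy(), weights=c.weights.copy())
    x_old = np.linspace(0.0, 1.0, L)
    x_new = np.linspace(0.0, 1.0, L_target)
    points = np.empty((L_target, c.n_features))
    for s in range(c.n_features):
        points[:, s] = np.interp(x_new, x_old, c.points[:, s])
    weights = np.interp(x_new, x_old, c.weights)
    # endpoints exact regardless of float grid round-off
    points[0], points[-1] = c.points[0], c.points[-1]
    weights[0], weights[-1] = c.weights[0], c.weights[-1]
    return ConsensusTrajectory(points=points, weights=weights)


def build_consensus(
    trajectories: Sequence[IndividualTrajectory],
    order: Sequence[int],
    consensus_length: int = DEFAULT_CONSENSUS_LENGTH,
    cost_metric: str = "euclidean",
) -> ConsensusTrajectory:
    """Progressively merge individual trajectories in the given order.

    The consensus starts as the first trajectory in ``order``; each remaining
    trajectory is aligned to the running consensus, averaged along the
    optimal path, and the result resampled to ``consensus_length``.
    Deterministic given ``order``.
    """
    if len(trajectories) < 2:
        raise ValueError("need >= 2 trajectories to build a consensus")
    if sorted(order) != list(range(len(trajectories))):
        raise ValueError("order must be a permutation of the trajectory indices")
    first = trajectories[order[0]].points
    consensus = ConsensusTrajectory(points=first.copy(), weights=np.ones(first.shape[0]))
    for idx in order[1:]:
        nxt = trajectories[idx].points
        path = pairwise_align(consensus.points, nxt, cost_metric)
        merged = merge_along_path(
            consensus.points, nxt, path, weights_A=consensus.weights
        )
        consensus = resample_consensus(merged, consensus_length)
    return consensus


@dataclass
class TrajectoryModel:
    """Fitted progression model: seed, scale, consensus ensemble, seed of RNG."""

    seed: SeedSet
    standardization: StandardizationParams
    ensemble: list[ConsensusTrajectory]
    hyperparams: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ensemble) < 1:
            raise ValueError("ensemble must hold at least one consensus trajectory")
        S = self.seed.size
        for c in self.ensemble:
            if c.n_features != S:
                raise ValueError("consensus dimension does not match seed size")

    @property
    def n_members(self) -> int:
        return len(self.ensemble)

    @property
    def cost_metric(self) -> str:
        return self.hyperparams.get("cost_metric", "euclidean")


def fit(
    dataset: LongitudinalDataset,
    seed: SeedSet | Sequence[str] | None = None,
    K: int = DEFAULT_K,
    G: int = DEFAULT_GRID_SIZE,
    consensus_length: int = DEFAULT_CONSENSUS_LENGTH,
    n_members: int = DEFAULT_N_MEMBERS,
    cost_metric: str = "euclidean",
    rng_seed: int = 0,
    rho_min: float = DEFAULT_RHO_MIN,
    consistency_min: float = DEFAULT_CONSISTENCY_MIN,
    subsample_frac: float | None = None,
    allow_ties: bool = False,
) -> TrajectoryModel:
    """Fit a trajectory model end to end.

    Resolves the seed (user list bypasses selection entirely), fits
    standardization on all training samples, builds per-individual
    trajectories, and generates ``n_members`` consensus trajectories, each
    from an independent uniformly-random permutation of individual order
    drawn from ``rng_seed`` (optionally on a random subset of individuals
    when ``subsample_frac`` is set).  Identical inputs and seed reproduce the
    model bit-for-bit.
    """
    report = validate_dataset(dataset)
    if not report.ok:
        raise ValueError(
            f"individuals with fewer than 3 samples: {report.flagged_individuals}; "
            "drop them with subset_individuals() before fitting"
        )
    if seed is None:
        seed_set = select_seed(dataset, K=K, G=G, rho_min=rho_min,
                               consistency_min=consistency_min)
    elif isinstance(seed, SeedSet):
        seed_set = seed
    else:
        seed_set = seed_from_features(dataset, list(seed), G=G, rho_min=rho_min)

    params = fit_standardization(dataset, seed_set.feature_names)
    individuals = dataset.individual_ids
    trajectories = [
        build_trajectory(dataset, ind, seed_set.feature_names, params, G,
                         allow_ties=allow_ties)
        for ind in individuals
    ]

    rng = np.random.default_rng(rng_seed)
    n_ind = len(trajectories)
    ensemble: list[ConsensusTrajectory] = []
    for _ in range(n_members):
        order = rng.permutation(n_ind)
        if subsample_frac is not None:
            k = max(2, int(np.ceil(subsample_frac * n_ind)))
            order = order[:k]
            subset = [trajectories[i] for i in order]
            c = build_consensus(subset, list(range(k)), consensus_length, cost_metric)
        else:
            c = build_consensus(trajectories, list(order), consensus_length, cost_metric)
        ensemble.append(c)

    return TrajectoryModel(
        seed=seed_set,
        standardization=params,
        ensemble=ensemble,
        hyperparams={
            "G": G,
            "consensus_length": consensus_length,
            "n_members": n_members,
            "cost_metric": cost_metric,
            "subsample_frac": subsample_frac,
        },
        rng_seed=rng_seed,
    )
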