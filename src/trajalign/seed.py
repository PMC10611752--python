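"""Conserved-dynamics seed selection.

The alignment needs a common ground: a small set of features whose
within-individual dynamics are monotone and loosely similar across
individuals.  Those features need not be drivers of progression — their
shared dynamics is what makes per-individual trajectories comparable.

Scoring works on *raw* per-individual profiles interpolated to a common
scaled-time grid; Pearson and Spearman are location/scale free, so no
standardization is needed (or wanted) at this stage.  Seed detection is
deliberately limited to increasing or decreasing features; non-monotone
dynamics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_GRID_SIZE,
    LongitudinalDataset,
    scale_times,
    validate_dataset,
)

__all__ = [
    "SeedSet",
    "score_feature_conservation",
    "score_monotone_consistency",
    "select_seed",
    "seed_from_features",
]

DEFAULT_K = 50
DEFAULT_RHO_MIN = 0.3
DEFAULT_CONSISTENCY_MIN = 0.7


@dataclass
class SeedSet:
    """Ordered conserved-dynamics seed: features, scores and trend signs.

    When ``provenance == "computed"`` the list is sorted by conservation
    score, non-increasing.  User-predefined seeds keep the user's order;
    scores are computed where defined (else NaN) but are informational only.
    """

    feature_names: list[str]
    conservation_scores: np.ndarray
    trend_signs: np.ndarray
    provenance: str = "computed"

    def __post_init__(self) -> None:
        self.conservation_scores = np.asarray(self.conservation_scores, dtype=float)
        self.trend_signs = np.asarray(self.trend_signs, dtype=int)
        if len(self.feature_names) < 2:
            raise ValueError("a seed needs at least 2 features")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("seed features must be unique")

    @property
    def size(self) -> int:
        return len(self.feature_names)


def _interpolated_profiles(
    dataset: LongitudinalDataset, feature: str, G: int
) -> np.ndarray | None:
    """Per-individual raw profiles on a uniform scaled-time grid (I x G).

    Returns ``None`` (the "excluded" sentinel) when any individual has zero
    variance in this feature or any value is NaN — a flat profile carries no
    dynamics and must not be rewarded with a numeric score.
    """
    inds = dataset.individual_ids
    if len(inds) < 2:
        raise ValueError("need at least 2 individuals to score conservation")
    row = dataset.feature_index(feature)[0]
    grid_x = np.linspace(0.0, 1.0, G)
    out = np.empty((len(inds), G))
    for i, ind in enumerate(inds):
        cols = dataset.columns_for(ind)
        vals = dataset.values[row, cols]
        if np.isnan(vals).any() or np.std(vals) == 0:
            return None
        times = np.array([dataset.samples[c].time for c in cols])
        scaled = scale_times(times)
        out[i] = np.interp(grid_x, scaled, vals)
    return out


def score_feature_conservation(
    dataset: LongitudinalDataset, feature: str, G: int = DEFAULT_GRID_SIZE
) -> float | None:
    """Mean pairwise-Pearson similarity of a feature's dynamics across individuals.

    Each individual's profile is interpolated to ``G`` uniform scaled-time
    points; the score is the mean Pearson correlation over all unordered
    pairs of individuals, in [-1, 1].  ``None`` means the feature is excluded
    (NaN or a flat profile in some individual).
    """
    profiles = _interpolated_profiles(dataset, feature, G)
    if profiles is None:
        return None
    return _mean_pairwise_pearson(profiles)


def _mean_pairwise_pearson(profiles: np.ndarray) -> float:
    # rows already guaranteed non-constant on the raw samples; interpolation
    # can still flatten a row, guard the division
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        return None  # interpolated profile degenerate -> excluded
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    iu = np.triu_indices(len(profiles), k=1)
    return float(np.clip(corr[iu], -1.0, 1.0).mean())


def score_monotone_consistency(
    dataset: LongitudinalDataset,
    feature: str,
    G: int = DEFAULT_GRID_SIZE,
    rho_min: float = DEFAULT_RHO_MIN,
) -> tuple[float, int] | None:
    """Fraction of individuals sharing a monotone trend, and the trend sign.

    Per individual: Spearman correlation of the interpolated profile with
    grid position.  The sign is the majority sign over individuals (ties
    break to +1, for determinism); consistency is the fraction whose sign
    matches the majority *and* whose \\|Spearman\\| >= ``rho_min``.
    """
    profiles = _interpolated_profiles(dataset, feature, G)
    if profiles is None:
        return None
    rhos = _spearman_vs_position(profiles)
    signs = np.sign(rhos)
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    majority = 1 if n_pos >= n_neg else -1
    match = (signs == majority) & (np.abs(rhos) >= rho_min)
    return float(match.mean()), majority


def _spearman_vs_position(profiles: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation against grid index (ties mid-ranked)."""
    G = profiles.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, profiles)
    pos = np.arange(1, G + 1, dtype=float)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    pc = pos - pos.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ pc) / denom
    return np.where(np.isfinite(rho), rho, 0.0)


def select_seed(
    dataset: LongitudinalDataset,
    K: int = DEFAULT_K,
    G: int = DEFAULT_GRID_SIZE,
    rho_min: float = DEFAULT_RHO_MIN,
    consistency_min: float = DEFAULT_CONSISTENCY_MIN,
) -> SeedSet:
    """Unsupervised seed selection.

    Candidates are features that (a) are scoreable (no NaN, no flat
    per-individual profile), and (b) pass the monotone-consistency filter at
    ``consistency_min``.  Candidates are ranked by conservation score,
    descending, ties broken by feature name, and the top ``K`` returned.
    Deterministic given the dataset; invariant to matrix row order.
    """
    report = validate_dataset(dataset)
    excluded = report.excluded_features
    records: list[tuple[float, str, int]] = []
    for feature in dataset.feature_names:
        if feature in excluded:
            continue
        mono = score_monotone_consistency(dataset, feature, G, rho_min)
        if mono is None:
            continue
        consistency, sign = mono
        if consistency < consistency_min:
            continue
        score = score_feature_conservation(dataset, feature, G)
        if score is None:
            continue
        records.append((score, feature, sign))
    if not records:
        raise ValueError(
            "no feature passed the monotone-consistency filter; consider a "
            "user-predefined seed or lower thresholds"
        )
    # descending score, lexicographic feature name on ties
    records.sort(key=lambda r: (-r[0], r[1]))
    if len(records) < K:
        import warnings

        warnings.warn(
            f"only {len(records)} candidate features passed the filter; "
            f"returning all of them (requested K={K})",
            stacklevel=2,
        )
    top = records[:K]
    return SeedSet(
        feature_names=[r[1] for r in top],
        conservation_scores=np.array([r[0] for r in top]),
        trend_signs=np.array([r[2] for r in top]),
        provenance="computed",
    )


def seed_from_features(
    dataset: LongitudinalDataset,
    features: list[str],
    G: int = DEFAULT_GRID_SIZE,
    rho_min: float = DEFAULT_RHO_MIN,
) -> SeedSet:
    """Wrap a user-predefined feature list as a SeedSet (no filtering applied).

    Selection is bypassed entirely; conservation scores and trend signs are
    computed where defined (NaN / sign 0 otherwise) for reporting only.
    """
    dataset.feature_index(features)  # raises listing missing features
    scores = np.full(len(features), np.nan)
    signs = np.zeros(len(features), dtype=int)
    for i, f in enumerate(features):
        s = score_feature_conservation(dataset, f, G)
        if s is not None:
            scores[i] = s
        mono = score_monotone_consistency(dataset, f, G, rho_min)
        if mono is not None:
            signs[i] = mono[1]
    return SeedSet(
        feature_names=list(features),
        conservation_scores=scores,
        trend_signs=signs,
        provenance="user_predefined",
    )
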