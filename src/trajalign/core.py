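"""Longitudinal data containers, validation, standardization and trajectories.

A cohort is a feature x sample matrix plus per-sample annotations mapping each
sample to an individual and a collection time.  Time is meaningful only
*within* an individual: it orders that individual's samples and is min-max
scaled to [0, 1] before any cross-individual comparison.  Absolute units
(hours, days, years) never cross individuals — the whole premise of disease
pseudotime is that chronological time is not comparable across them.

Each individual needs at least :data:`MIN_SAMPLES_PER_INDIVIDUAL` samples to
define a trajectory; shorter series cannot be interpolated meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIN_SAMPLES_PER_INDIVIDUAL",
    "DEFAULT_GRID_SIZE",
    "SampleRecord",
    "LongitudinalDataset",
    "ValidationReport",
    "validate_dataset",
    "StandardizationParams",
    "fit_standardization",
    "apply_standardization",
    "invert_standardization",
    "IndividualTrajectory",
    "build_trajectory",
]

#: Minimum number of time points an individual must contribute.
MIN_SAMPLES_PER_INDIVIDUAL = 3

#: Default number of uniform grid positions used when interpolating
#: per-individual profiles onto scaled time.  Comparable to the densest
#: cohorts this kind of model is built on (10-15 time points per individual)
#: without inventing resolution.
DEFAULT_GRID_SIZE = 10


@dataclass(frozen=True)
class SampleRecord:
    """One profiled sample: who it came from and when it was collected."""

    sample_id: str
    individual_id: str
    time: float


@dataclass
class LongitudinalDataset:
    """Feature x sample matrix with per-sample (individual, time) annotations.

    Parameters
    ----------
    feature_names
        F unique feature identifiers (row labels of ``values``).
    samples
        N :class:`SampleRecord`, one per column of ``values``.
    values
        F x N numeric matrix; ``values[f, n]`` is feature ``f`` measured in
        sample ``n``.
    """

    feature_names: list[str]
    samples: list[SampleRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D feature x sample matrix")
        if self.values.shape != (len(self.feature_names), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_names)} features x {len(self.samples)} samples"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def individual_ids(self) -> list[str]:
        """Unique individual ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.individual_id, None)
        return list(seen)

    def feature_index(self, names: list[str] | str) -> np.ndarray:
        """Row indices for ``names``; raises listing any missing features."""
        if isinstance(names, str):
            names = [names]
        lookup = {f: i for i, f in enumerate(self.feature_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"features not in dataset: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def columns_for(self, individual_id: str) -> np.ndarray:
        """Column indices of one individual's samples, time-sorted (stable)."""
        cols = [i for i, s in enumerate(self.samples) if s.individual_id == individual_id]
        if not cols:
            raise KeyError(f"unknown individual: {individual_id}")
        times = np.array([self.samples[i].time for i in cols])
        return np.array(cols, dtype=int)[np.argsort(times, kind="stable")]

    def subset_individuals(self, individual_ids: list[str]) -> "LongitudinalDataset":
        """New dataset restricted to the given individuals (column order kept)."""
        keep = set(individual_ids)
        cols = [i for i, s in enumerate(self.samples) if s.individual_id in keep]
        return LongitudinalDataset(
            feature_names=list(self.feature_names),
            samples=[self.samples[i] for i in cols],
            values=self.values[:, cols].copy(),
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`.

    ``flagged_individuals`` have fewer than the minimum number of samples;
    ``features_with_nan`` and ``features_zero_variance`` are excluded from
    seed candidacy downstream but otherwise left in place.
    """

    samples_per_individual: dict[str, int] = field(default_factory=dict)
    flagged_individuals: list[str] = field(default_factory=list)
    features_with_nan: list[str] = field(default_factory=list)
    features_zero_variance: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flagged_individuals

    @property
    def excluded_features(self) -> set[str]:
        return set(self.features_with_nan) | set(self.features_zero_variance)


def validate_dataset(dataset: LongitudinalDataset) -> ValidationReport:
    """Check cohort structure; hard-error on malformed records, flag the rest.

    Hard errors (raise ``ValueError``): empty dataset, duplicated sample ids,
    non-finite collection times.  Soft problems (reported): individuals with
    fewer than three samples, features containing NaN, features with zero
    variance across all samples.
    """
    if dataset.n_samples == 0 or dataset.n_features == 0:
        raise ValueError("empty dataset")

    seen: set[str] = set()
    for s in dataset.samples:
        if s.sample_id in seen:
            raise ValueError(f"duplicated sample_id: {s.sample_id!r}")
        seen.add(s.sample_id)
        if not np.isfinite(s.time):
            raise ValueError(
                f"non-finite time for sample {s.sample_id!r} "
                f"(individual {s.individual_id!r}): {s.time!r}"
            )
    dupes = [f for f, c in _counts(dataset.feature_names).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicated feature names: {dupes}")

    report = ValidationReport()
    for ind in dataset.individual_ids:
        n = sum(1 for s in dataset.samples if s.individual_id == ind)
        report.samples_per_individual[ind] = n
        if n < MIN_SAMPLES_PER_INDIVIDUAL:
            report.flagged_individuals.append(ind)

    nan_rows = np.isnan(dataset.values).any(axis=1)
    with np.errstate(invalid="ignore"):
        flat_rows = np.nanstd(dataset.values, axis=1) == 0
    for f, is_nan, is_flat in zip(dataset.feature_names, nan_rows, flat_rows):
        if is_nan:
            report.features_with_nan.append(f)
        elif is_flat:
            report.features_zero_variance.append(f)
    return report


def _counts(items: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    """Per-feature z-scoring parameters fitted on the training cohort.

    New samples must be projected in the training feature scale, so the
    center (training mean) and scale (training sd, population convention)
    are stored with the model.
    """

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            bad = [f for f, s in zip(self.feature_names, self.scale) if s <= 0]
            raise ValueError(f"non-positive scale for features: {bad}")


def fit_standardization(
    dataset: LongitudinalDataset, feature_names: list[str]
) -> StandardizationParams:
    """Fit per-feature mean/sd over all training samples for ``feature_names``."""
    rows = dataset.feature_index(feature_names)
    sub = dataset.values[rows]
    center = sub.mean(axis=1)
    scale = sub.std(axis=1)
    zero = scale == 0
    if zero.any():
        bad = [feature_names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero variance across training samples for: {bad}")
    return StandardizationParams(list(feature_names), center, scale)


def apply_standardization(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Z-score a length-S vector or S x N matrix in the training scale."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(params.feature_names):
        raise ValueError(
            f"expected leading dimension {len(params.feature_names)}, got {values.shape[0]}"
        )
    if values.ndim == 1:
        return (values - params.center) / params.scale
    return (values - params.center[:, None]) / params.scale[:, None]


def invert_standardization(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return values * params.scale + params.center
    return values * params.scale[:, None] + params.center[:, None]


# ---------------------------------------------------------------------------
# Per-individual trajectories
# ---------------------------------------------------------------------------


@dataclass
class IndividualTrajectory:
    """One individual's seed-feature profile on a uniform scaled-time grid.

    ``grid`` is S x G: each seed feature standardized (training scale) and
    linearly interpolated onto G equally spaced positions of within-individual
    scaled time in [0, 1].
    """

    individual_id: str
    sample_ids: list[str]
    scaled_times: np.ndarray
    grid: np.ndarray

    @property
    def points(self) -> np.ndarray:
        """G x S point-sequence view used by the alignment."""
        return self.grid.T


def scale_times(times: np.ndarray, *, allow_ties: bool = False) -> np.ndarray:
    """Min-max scale an individual's sorted times onto [0, 1].

    Duplicate times are an error by default: ordering is the only use this
    model makes of time, and silent tie-breaking hides data problems.  With
    ``allow_ties=True`` ties are resolved by stable input order with an
    epsilon jitter before rescaling.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if np.any(np.diff(times) == 0):
        if not allow_ties:
            raise ValueError(
                "duplicate times within individual; pass allow_ties=True to "
                "break ties by stable input order"
            )
        span = times[-1] - times[0]
        eps = (span if span > 0 else 1.0) * 1e-9
        times = times + np.arange(len(times)) * eps
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("all times identical; cannot scale")
    return (times - times[0]) / span


def build_trajectory(
    dataset: LongitudinalDataset,
    individual_id: str,
    seed_features: list[str],
    params: StandardizationParams,
    G: int = DEFAULT_GRID_SIZE,
    *,
    allow_ties: bool = False,
) -> IndividualTrajectory:
    """Interpolate one individual's standardized seed profile onto G grid points.

    Samples are time-sorted, times min-max scaled to [0, 1], each seed feature
    standardized with the training ``params`` and then piecewise-linearly
    interpolated onto ``G`` equally spaced scaled-time positions.  Linear
    (not spline) interpolation: series of 3-15 points make splines unstable,
    and linear interpolation is deterministic and monotone-preserving.
    """
    if G < 3:
        raise ValueError("G must be >= 3")
    cols = dataset.columns_for(individual_id)
    if len(cols) < MIN_SAMPLES_PER_INDIVIDUAL:
        raise ValueError(
            f"individual {individual_id!r} has {len(cols)} samples; "
            f"need >= {MIN_SAMPLES_PER_INDIVIDUAL}"
        )
    times = np.array([dataset.samples[i].time for i in cols])
    scaled = scale_times(times, allow_ties=allow_ties)

    rows = dataset.feature_index(seed_features)
    raw = dataset.values[np.ix_(rows, cols)]
    std = apply_standardization(raw, params)

    grid_x = np.linspace(0.0, 1.0, G)
    grid = np.empty((len(seed_features), G))
    for s in range(len(seed_features)):
        grid[s] = np.interp(grid_x, scaled, std[s])
    return IndividualTrajectory(
        individual_id=individual_id,
        sample_ids=[dataset.samples[i].sample_id for i in cols],
        scaled_times=scaled,
        grid=grid,
    )
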