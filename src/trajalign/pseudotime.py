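"""Disease pseudotime estimation: project samples onto the consensus ensemble.

A sample's pseudotime is its relative position along the shared progression
axis.  For each ensemble member the sample is placed at its nearest consensus
point (same cost metric the alignment used) and the index is normalized to
[0, 1]; positions are then combined across members (mean by default), with
their standard deviation reported as a dispersion/uncertainty proxy.

Prediction is time-agnostic: neither the metadata time column nor the
individual labels are consulted, so the same model scores training samples,
held-out individuals, or cross-sectional cohorts alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .align import TrajectoryModel
from .core import LongitudinalDataset, apply_standardization

__all__ = [
    "PseudotimeEstimate",
    "project_sample",
    "predict",
    "estimates_frame",
    "plot_pseudotime_vs_time",
]


@dataclass
class PseudotimeEstimate:
    """Per-sample position in [0, 1] with per-member positions and dispersion."""

    sample_id: str
    pseudotime: float
    member_positions: np.ndarray
    dispersion: float


def _member_positions(model: TrajectoryModel, std_vectors: np.ndarray) -> np.ndarray:
    """Positions (N x B) of standardized sample vectors on each ensemble member.

    ``std_vectors`` is N x S (standardized seed space).  Ties at the argmin
    go to the smallest consensus index.
    """
    metric = "correlation" if model.cost_metric == "pearson" else "euclidean"
    out = np.empty((std_vectors.shape[0], model.n_members))
    for b, c in enumerate(model.ensemble):
        d = cdist(std_vectors, c.points, metric=metric)
        out[:, b] = np.argmin(d, axis=1) / (c.length - 1)
    return out


def _resolve_vector(
    model: TrajectoryModel, vector: np.ndarray, feature_names: Sequence[str] | None
) -> np.ndarray:
    vector = np.asarray(vector, dtype=float)
    seed_features = model.seed.feature_names
    if feature_names is None:
        if vector.shape[0] != len(seed_features):
            raise ValueError(
                "without feature_names the vector must already be in seed "
                f"order (length {len(seed_features)}, got {vector.shape[0]})"
            )
        sub = vector
    else:
        lookup = {f: i for i, f in enumerate(feature_names)}
        missing = [f for f in seed_features if f not in lookup]
        if missing:
            raise ValueError(f"sample is missing seed features: {missing}")
        sub = vector[[lookup[f] for f in seed_features]]
    if not np.all(np.isfinite(sub)):
        bad = [f for f, v in zip(seed_features, sub) if not np.isfinite(v)]
        raise ValueError(f"non-finite seed-feature values for: {bad}")
    return sub


def project_sample(
    model: TrajectoryModel,
    vector: np.ndarray,
    feature_names: Sequence[str] | None = None,
    sample_id: str = "",
    combine: str = "mean",
) -> PseudotimeEstimate:
    """Project a single feature vector onto the ensemble.

    ``vector`` may be a full-length feature vector accompanied by
    ``feature_names``, or already restricted to (and ordered as) the model's
    seed features.
    """
    sub = _resolve_vector(model, vector, feature_names)
    std = apply_standardization(sub, model.standardization)
    positions = _member_positions(model, std[None, :])[0]
    return _combine(sample_id, positions, combine)


def _combine(sample_id: str, positions: np.ndarray, combine: str) -> PseudotimeEstimate:
    if combine == "mean":
        pt = float(positions.mean())
    elif combine == "median":
        pt = float(np.median(positions))
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return PseudotimeEstimate(
        sample_id=sample_id,
        pseudotime=pt,
        member_positions=positions,
        dispersion=float(positions.std()),
    )


def predict(
    model: TrajectoryModel,
    dataset: LongitudinalDataset,
    combine: str = "mean",
) -> list[PseudotimeEstimate]:
    """Pseudotime for every sample in a dataset, in input column order.

    Only the expression matrix is used; sample times and individual ids in
    the metadata are ignored (and may be absent or wrong) at prediction.
    """
    rows = dataset.feature_index(model.seed.feature_names)
    sub = dataset.values[rows]
    if not np.all(np.isfinite(sub)):
        bad_cols = np.flatnonzero(~np.all(np.isfinite(sub), axis=0))
        bad = [dataset.samples[c].sample_id for c in bad_cols]
        raise ValueError(f"non-finite seed-feature values in samples: {bad}")
    std = apply_standardization(sub, model.standardization).T  # N x S
    positions = _member_positions(model, std)
    return [
        _combine(s.sample_id, positions[i], combine)
        for i, s in enumerate(dataset.samples)
    ]


def estimates_frame(estimates: list[PseudotimeEstimate]) -> pd.DataFrame:
    """Tidy table of estimates: sample_id, pseudotime, dispersion."""
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "pseudotime": [e.pseudotime for e in estimates],
            "dispersion": [e.dispersion for e in estimates],
        }
    )


def plot_pseudotime_vs_time(
    dataset: LongitudinalDataset,
    estimates: list[PseudotimeEstimate],
    path: str | None = None,
):
    """Minimal diagnostic figure: pseudotime against chronological time.

    One line per individual.  Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pt = {e.sample_id: e.pseudotime for e in estimates}
    fig, ax = plt.subplots(figsize=(6, 4))
    for ind in dataset.individual_ids:
        cols = dataset.columns_for(ind)
        times = [dataset.samples[c].time for c in cols]
        ys = [pt[dataset.samples[c].sample_id] for c in cols]
        ax.plot(times, ys, marker="o", alpha=0.7, label=ind)
    ax.set_xlabel("chronological time (cohort units)")
    ax.set_ylabel("disease pseudotime")
    ax.set_ylim(-0.02, 1.02)
    if len(dataset.individual_ids) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
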