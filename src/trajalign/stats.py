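"""Pseudotime-based downstream statistics.

Four analyses built on an inferred progression axis:

* per-feature association — Pearson correlation with the axis plus a
  polynomial-regression F-test against the intercept-only model, FDR
  corrected (Benjamini-Hochberg) across features;
* dual-axis classification — which features associate with pseudotime, with
  chronological time, with both, or with neither, at one or several q-value
  cutoffs;
* pathway enrichment — per gene set, a two-sample Kolmogorov-Smirnov test on
  the correlation coefficients of member vs background genes, scored as
  -log10(p);
* transition-point detection — a grid search along pseudotime for the
  threshold that best separates a per-sample scalar (e.g. tumor purity) into
  pre/post groups, with an optional permutation calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "associate_features",
    "classify_dual_axis",
    "dual_axis_counts",
    "pathway_enrichment",
    "TransitionPoint",
    "detect_transition_point",
    "transition_permutation_pvalue",
]

DUAL_AXIS_LABELS = ("both", "pseudotime_only", "time_only", "neither")
DEFAULT_POLY_DEGREE = 2


def associate_features(
    values: np.ndarray,
    axis: np.ndarray,
    feature_names: list[str] | None = None,
    degree: int = DEFAULT_POLY_DEGREE,
) -> pd.DataFrame:
    """Associate every feature with a progression axis.

    Per feature: Pearson r against ``axis``; p-value from an F-test of the
    degree-``degree`` polynomial regression of the feature on the axis
    against the intercept-only model; q-values by Benjamini-Hochberg across
    all features.  The default degree of 2 captures saturating dynamics
    without overfitting short series.

    Constant features are recorded with r = 0, p = 1 and ``constant=True``
    rather than NaN.  A constant axis is an error.

    Returns a DataFrame with columns ``feature, pearson_r, p_value, q_value,
    constant``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    axis = np.asarray(axis, dtype=float)
    F, N = values.shape
    if axis.shape != (N,):
        raise ValueError(f"axis length {axis.shape} does not match {N} samples")
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis contains non-finite values")
    if np.std(axis) == 0:
        raise ValueError("axis is constant; association is undefined")
    if N < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} samples, got {N}")
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(F)]

    yc = values - values.mean(axis=1, keepdims=True)
    ss_tot = (yc**2).sum(axis=1)
    constant = ss_tot == 0

    ac = axis - axis.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ ac) / (np.sqrt(ss_tot) * np.linalg.norm(ac))
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))

    # one shared design matrix -> vectorized OLS across features
    X = np.vander(axis, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    resid = values.T - X @ beta
    ss_res = (resid**2).sum(axis=0)
    df_num = degree
    df_den = N - degree - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat = ((ss_tot - ss_res) / df_num) / (ss_res / df_den)
    p = sps.f.sf(fstat, df_num, df_den)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": feature_names,
            "pearson_r": r,
            "p_value": p,
            "q_value": q,
            "constant": constant,
        }
    )


def classify_dual_axis(
    q_pseudotime: np.ndarray, q_time: np.ndarray, cutoff: float
) -> np.ndarray:
    """Label each feature by which axes it associates with at ``cutoff``.

    Labels: ``both``, ``pseudotime_only``, ``time_only``, ``neither``.
    """
    q_pt = np.asarray(q_pseudotime, dtype=float)
    q_t = np.asarray(q_time, dtype=float)
    if q_pt.shape != q_t.shape:
        raise ValueError("q-value vectors must have equal length")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    pt_sig = q_pt < cutoff
    t_sig = q_t < cutoff
    labels = np.full(q_pt.shape, "neither", dtype=object)
    labels[pt_sig & t_sig] = "both"
    labels[pt_sig & ~t_sig] = "pseudotime_only"
    labels[~pt_sig & t_sig] = "time_only"
    return labels


def dual_axis_counts(
    q_pseudotime: np.ndarray,
    q_time: np.ndarray,
    cutoffs: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
) -> pd.DataFrame:
    """Label counts across a sweep of q-value cutoffs (rows sum to F)."""
    rows = []
    for cutoff in cutoffs:
        labels = classify_dual_axis(q_pseudotime, q_time, cutoff)
        row = {"cutoff": cutoff}
        for lab in DUAL_AXIS_LABELS:
            row[lab] = int((labels == lab).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_enrichment(
    corrs: pd.Series,
    gene_sets: dict[str, list[str]],
    alternative: str = "two-sided",
    signed: bool = False,
) -> pd.DataFrame:
    """KS enrichment of gene sets on axis-correlation coefficients.

    ``corrs`` maps feature name -> Pearson correlation with the axis.  Each
    set's member correlations are compared with the background (all
    non-member features) by a two-sample KS test; the enrichment score is
    -log10(p).  Sets with fewer than 2 members present among the features
    are skipped with a warning.  With ``signed=True`` each set is tested
    once per direction with one-sided alternatives, separating positive and
    negative associations.

    Returns a DataFrame with columns ``pathway, n_members, ks_statistic,
    p_value, score`` (plus ``direction`` when signed).
    """
    import warnings

    if not isinstance(corrs, pd.Series):
        raise TypeError("corrs must be a pandas Series indexed by feature name")
    features = set(corrs.index)
    rows = []
    modes = (
        [("less", "positive"), ("greater", "negative")] if signed
        else [(alternative, None)]
    )
    for name, members in gene_sets.items():
        present = sorted(set(members) & features)
        if len(present) < 2:
            warnings.warn(
                f"gene set {name!r}: {len(present)} member(s) present; skipped",
                stacklevel=2,
            )
            continue
        member_vals = corrs.loc[present].to_numpy()
        background = corrs.drop(index=present).to_numpy()
        if background.size == 0:
            raise ValueError(f"gene set {name!r} leaves an empty background")
        for alt, direction in modes:
            res = sps.ks_2samp(member_vals, background, alternative=alt)
            p = float(np.clip(res.pvalue, np.finfo(float).tiny, 1.0))
            row = {
                "pathway": name,
                "n_members": len(present),
                "ks_statistic": float(res.statistic),
                "p_value": p,
                "score": float(-np.log10(p)),
            }
            if direction is not None:
                row["direction"] = direction
            rows.append(row)
    cols = ["pathway", "n_members", "ks_statistic", "p_value", "score"]
    if signed:
        cols.append("direction")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Transition point along pseudotime
# ---------------------------------------------------------------------------


@dataclass
class TransitionPoint:
    """Best pre/post split of a scalar along pseudotime.

    ``statistic`` is the absolute Welch t comparing samples below vs above
    ``threshold``; ``degenerate`` marks an all-identical input (statistic 0,
    threshold at the grid midpoint).  ``p_value`` is filled by the
    permutation calibration when requested.
    """

    threshold: float
    statistic: float
    degenerate: bool = False
    p_value: float | None = None


def _scan_thresholds(
    y_sorted: np.ndarray,
    pt_sorted: np.ndarray,
    thresholds: np.ndarray,
    min_group_size: int,
) -> np.ndarray:
    """Absolute Welch t at every threshold (NaN where a group is too small).

    Operates on samples pre-sorted by pseudotime so that every split is a
    prefix/suffix; prefix sums make the whole scan O(N + T).
    """
    N = len(y_sorted)
    cs = np.concatenate([[0.0], np.cumsum(y_sorted)])
    cs2 = np.concatenate([[0.0], np.cumsum(y_sorted**2)])
    n1 = np.searchsorted(pt_sorted, thresholds, side="right")
    n2 = N - n1
    valid = (n1 >= min_group_size) & (n2 >= min_group_size)
    out = np.full(len(thresholds), np.nan)
    if not valid.any():
        return out
    n1v = n1[valid]
    n2v = n2[valid]
    s1 = cs[n1v]
    s2 = cs[-1] - s1
    q1 = cs2[n1v]
    q2 = cs2[-1] - q1
    m1 = s1 / n1v
    m2 = s2 / n2v
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = np.maximum(q1 - n1v * m1**2, 0.0) / (n1v - 1)
        v2 = np.maximum(q2 - n2v * m2**2, 0.0) / (n2v - 1)
        se = np.sqrt(v1 / n1v + v2 / n2v)
        t = np.abs(m1 - m2) / se
    t = np.where(np.isfinite(t), t, np.where(np.abs(m1 - m2) > 0, np.inf, 0.0))
    out[valid] = t
    return out


def detect_transition_point(
    y: np.ndarray,
    pseudotime: np.ndarray,
    grid_step: float = 0.01,
    min_group_size: int = 5,
    grid_range: tuple[float, float] = (0.1, 0.9),
) -> TransitionPoint:
    """Find the pseudotime threshold that best splits ``y`` into pre/post.

    Candidate thresholds are a uniform grid over ``grid_range`` with step
    ``grid_step``; each split's strength is the absolute Welch-t statistic
    between the two groups (both must contain ``min_group_size`` samples).
    Ties go to the smallest threshold.
    """
    y = np.asarray(y, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    if y.shape != pt.shape:
        raise ValueError("y and pseudotime must have the same length")
    if len(y) < 2 * min_group_size:
        raise ValueError(
            f"need at least {2 * min_group_size} samples for groups of "
            f"{min_group_size}"
        )
    lo, hi = grid_range
    thresholds = np.arange(lo, hi + grid_step / 2, grid_step)
    if np.all(y == y[0]):
        return TransitionPoint(
            threshold=float(thresholds[len(thresholds) // 2]),
            statistic=0.0,
            degenerate=True,
        )
    order = np.argsort(pt, kind="stable")
    t = _scan_thresholds(y[order], pt[order], thresholds, min_group_size)
    if np.all(np.isnan(t)):
        raise ValueError("no threshold yields two groups of the minimum size")
    best = int(np.nanargmax(t))
    return TransitionPoint(threshold=float(thresholds[best]), statistic=float(t[best]))


def transition_permutation_pvalue(
    y: np.ndarray,
    pseudotime: np.ndarray,
    n_permutations: int = 199,
    rng: np.random.Generator | int | None = None,
    grid_step: float = 0.01,
    min_group_size: int = 5,
    grid_range: tuple[float, float] = (0.1, 0.9),
) -> TransitionPoint:
    """Permutation-calibrated transition point.

    The observed max-\\|t\\| is compared with its null distribution under
    random reassignment of ``y`` to pseudotime positions; the p-value uses
    the add-one convention ``(1 + #{null >= observed}) / (1 + B)``.
    """
    rng = np.random.default_rng(rng)
    obs = detect_transition_point(y, pseudotime, grid_step, min_group_size, grid_range)
    if obs.degenerate:
        obs.p_value = 1.0
        return obs
    pt = np.asarray(pseudotime, dtype=float)
    order = np.argsort(pt, kind="stable")
    pt_sorted = pt[order]
    lo, hi = grid_range
    thresholds = np.arange(lo, hi + grid_step / 2, grid_step)
    y_arr = np.asarray(y, dtype=float)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y_arr)
        t = _scan_thresholds(perm, pt_sorted, thresholds, min_group_size)
        if np.nanmax(t) >= obs.statistic:
            exceed += 1
    obs.p_value = (1 + exceed) / (1 + n_permutations)
    return obs
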