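"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: path enumeration instead
of dynamic programming, the textbook step-up definition of BH, a direct
ECDF-gap scan for the KS statistic, and an explicit per-threshold Welch scan.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def enumerate_monotone_paths(m: int, n: int):
    """Yield every monotone path from (0, 0) to (m-1, n-1)."""

    def rec(i, j, path):
        if (i, j) == (m - 1, n - 1):
            yield path
            return
        if i + 1 < m and j + 1 < n:
            yield from rec(i + 1, j + 1, path + [(i + 1, j + 1)])
        if i + 1 < m:
            yield from rec(i + 1, j, path + [(i + 1, j)])
        if j + 1 < n:
            yield from rec(i, j + 1, path + [(i, j + 1)])

    yield from rec(0, 0, [(0, 0)])


def brute_force_min_cost(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum Euclidean path cost over all monotone alignments (exhaustive)."""
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    best = np.inf
    for path in enumerate_monotone_paths(len(A), len(B)):
        cost = sum(d[i, j] for i, j in path)
        best = min(best, cost)
    return best


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(pvals, dtype=float)
    F = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(F)
    running_min = 1.0
    for rank_from_top in range(F, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * F / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def ks_statistic_ecdf(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic as the max ECDF gap over all pooled values."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    pooled = np.concatenate([x, y])
    gaps = [
        abs(
            np.searchsorted(x, v, side="right") / len(x)
            - np.searchsorted(y, v, side="right") / len(y)
        )
        for v in pooled
    ]
    return max(gaps)


def welch_scan_best_threshold(
    y: np.ndarray,
    pt: np.ndarray,
    thresholds: np.ndarray,
    min_group_size: int,
) -> tuple[float, float]:
    """Best split by looping thresholds and calling scipy's Welch t directly."""
    best_t, best_thr = -np.inf, None
    for thr in thresholds:
        a = y[pt <= thr]
        b = y[pt > thr]
        if len(a) < min_group_size or len(b) < min_group_size:
            continue
        t = abs(sps.ttest_ind(a, b, equal_var=False).statistic)
        if t > best_t:
            best_t, best_thr = t, thr
    return best_thr, best_t
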