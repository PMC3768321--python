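"""Permutation and rank statistics supporting the disparity/rate analyses.

Mantel tests correlate two distance matrices (Pearson r, Spearman rho or
Kendall tau on the vectorized upper triangles), with significance from
random simultaneous row/column permutations of the second matrix.
npMANOVA (PERMANOVA) and ANOSIM test group structure in multivariate
scores / distances by label permutation.  Kruskal-Wallis and Mann-Whitney
wrap the tie-corrected scipy implementations.  Generalized differencing
removes linear trend and first-order autocorrelation from a time series
before correlation analysis, so that diversity-disparity correlations are
not driven by shared trends.

All permutation p-values use the +1 rule (the observed statistic counts
as one permutation), so ``p >= 1/(n_permutations + 1)``, and every test
records its statistic, permutation count and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from morphorates.distances import DistanceMatrix


@dataclass
class PermutationTestResult:
    statistic: float
    coefficient: str
    n_permutations: int
    p: float
    seed: "int | None" = None
    extra: "pd.DataFrame | None" = None

    def __post_init__(self) -> None:
        assert self.p >= 1.0 / (self.n_permutations + 1) - 1e-12


_COEFS = {
    "pearson": lambda a, b: scipy.stats.pearsonr(a, b)[0],
    "spearman": lambda a, b: scipy.stats.spearmanr(a, b)[0],
    "kendall": lambda a, b: scipy.stats.kendalltau(a, b)[0],
}


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    coef: str = "spearman",
    nperm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationTestResult:
    """Mantel test of association between two distance matrices.

    The coefficient is computed on the upper triangles; the null
    distribution permutes the taxa of ``d2`` (rows and columns together).
    Two-sided by default: permutations with ``|stat| >= |observed|`` count.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    n = d1.n
    if n < 3:
        raise ValueError("Mantel test needs at least three taxa")
    if coef not in _COEFS:
        raise ValueError(f"unknown coefficient {coef!r}")
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    stat_fn = _COEFS[coef]
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    observed = stat_fn(v1, d2.d[iu])
    rng = np.random.default_rng(seed)
    count = 1  # the observed ordering counts as one permutation
    for _ in range(nperm):
        perm = rng.permutation(n)
        stat = stat_fn(v1, d2.d[np.ix_(perm, perm)][iu])
        if alternative == "two-sided":
            if abs(stat) >= abs(observed) - 1e-12:
                count += 1
        elif alternative == "greater":
            if stat >= observed - 1e-12:
                count += 1
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationTestResult(
        statistic=float(observed),
        coefficient=coef,
        n_permutations=nperm,
        p=count / (nperm + 1),
        seed=seed,
    )


def subset_distances(d: DistanceMatrix, drop: "set[str] | list[str]") -> DistanceMatrix:
    """Delete the rows/columns of the given taxa (for exclusion re-runs)."""
    return d.drop(drop)


# ---------------------------------------------------------------------------
# npMANOVA (PERMANOVA) and ANOSIM
# ---------------------------------------------------------------------------


def _permanova_f(d2_sq: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F from a squared-distance matrix and integer group labels."""
    n = d2_sq.shape[0]
    labels = np.unique(groups)
    g = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2_sq[iu].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.where(groups == lab)[0]
        if len(idx) < 1:
            continue
        sub = d2_sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def npmanova(
    scores: np.ndarray,
    groups: "list[str] | np.ndarray",
    nperm: int = 9999,
    seed: int = 0,
    pairwise: bool = True,
) -> PermutationTestResult:
    """Non-parametric (permutational) MANOVA on multivariate scores.

    Euclidean distances among rows of ``scores``; pseudo-F from among- and
    within-group sums of squared distances; p by permuting group labels.
    With ``pairwise`` a post hoc table of all group pairs is attached
    (Bonferroni-adjusted p).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if scores.shape[0] != len(groups):
        raise ValueError("scores rows and group labels differ in length")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    d2_sq = squareform(pdist(scores)) ** 2
    result = _label_permutation_test(d2_sq, groups, _permanova_f, nperm, seed)
    result.coefficient = "pseudo-F"
    if pairwise:
        result.extra = _pairwise_tests(d2_sq, groups, _permanova_f, nperm, seed)
    return result


def _anosim_r(ranks: np.ndarray, groups: np.ndarray) -> float:
    n = ranks.shape[0]
    same = groups[:, None] == groups[None, :]
    iu = np.triu_indices(n, k=1)
    within = ranks[iu][same[iu]]
    between = ranks[iu][~same[iu]]
    m = n * (n - 1) / 2
    return (between.mean() - within.mean()) / (m / 2.0)


def anosim(
    d: DistanceMatrix,
    groups: "list[str] | np.ndarray",
    nperm: int = 9999,
    seed: int = 0,
) -> PermutationTestResult:
    """Analysis of similarity on a distance matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)``
    with mid-ranks for ties over the M = n(n-1)/2 pairs; p by label
    permutation.
    """
    groups = np.asarray(groups)
    if d.n != len(groups):
        raise ValueError("distance matrix and group labels differ in length")
    n = d.n
    iu = np.triu_indices(n, k=1)
    ranks_flat = scipy.stats.rankdata(d.d[iu])  # mid-ranks
    ranks = np.zeros((n, n))
    ranks[iu] = ranks_flat
    ranks = ranks + ranks.T
    result = _label_permutation_test(ranks, groups, _anosim_r, nperm, seed)
    result.coefficient = "R"
    return result


def _label_permutation_test(matrix, groups, stat_fn, nperm, seed) -> PermutationTestResult:
    observed = stat_fn(matrix, groups)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(nperm):
        stat = stat_fn(matrix, rng.permutation(groups))
        if stat >= observed - 1e-12:
            count += 1
    return PermutationTestResult(
        statistic=float(observed),
        coefficient="",
        n_permutations=nperm,
        p=count / (nperm + 1),
        seed=seed,
    )


def _pairwise_tests(d2_sq, groups, stat_fn, nperm, seed) -> pd.DataFrame:
    labels = list(np.unique(groups))
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            idx = np.where((groups == a) | (groups == b))[0]
            sub = d2_sq[np.ix_(idx, idx)]
            res = _label_permutation_test(sub, groups[idx], stat_fn, nperm, seed)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "statistic": res.statistic,
                    "p": res.p,
                    "p_bonferroni": min(res.p * n_pairs, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis(samples: "list[np.ndarray]") -> "tuple[float, float]":
    """Tie-corrected Kruskal-Wallis H and chi-square p (df = groups - 1)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> "tuple[float, float]":
    """Two-sided Mann-Whitney U with normal approximation and tie correction."""
    u, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def pairwise_mann_whitney(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided U tests, raw and Bonferroni-adjusted."""
    names = list(samples)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mann_whitney(samples[a], samples[b])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "U": u,
                    "p": p,
                    "p_bonferroni": min(p * n_pairs, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generalized differencing and diversity-disparity correlation
# ---------------------------------------------------------------------------


def generalized_differencing(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Remove linear trend and lag-1 autocorrelation from a time series.

    Fits ``series ~ times`` by OLS, estimates the first-order
    autocorrelation ``rho`` of the residuals, and returns the
    quasi-differenced residuals ``e_t - rho * e_{t-1}`` with the first
    element scaled by ``sqrt(1 - rho^2)`` (the exact AR(1) GLS transform).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape or series.ndim != 1:
        raise ValueError("series and times must be equal-length 1-D arrays")
    if len(series) < 4:
        raise ValueError("series too short to estimate autocorrelation (need >= 4)")
    slope, intercept = np.polyfit(times, series, 1)
    resid = series - (slope * times + intercept)
    denom = np.dot(resid, resid)
    rho = 0.0 if denom == 0 else float(np.dot(resid[1:], resid[:-1]) / denom)
    rho = float(np.clip(rho, -0.99, 0.99))
    out = np.empty_like(resid)
    out[0] = resid[0] * np.sqrt(1.0 - rho ** 2)
    out[1:] = resid[1:] - rho * resid[:-1]
    return out


def estimate_ar1(series: np.ndarray, times: np.ndarray) -> float:
    """Lag-1 autocorrelation of the detrended series (as used above)."""
    series = np.asarray(series, dtype=float)
    slope, intercept = np.polyfit(times, series, 1)
    resid = series - (slope * np.asarray(times, dtype=float) + intercept)
    denom = np.dot(resid, resid)
    return 0.0 if denom == 0 else float(np.dot(resid[1:], resid[:-1]) / denom)


def diversity_disparity_correlation(
    disparity: np.ndarray,
    diversity: np.ndarray,
    times: np.ndarray,
    differenced: bool = False,
    coef: str = "pearson",
) -> "tuple[float, float]":
    """Correlation between a disparity and a diversity time series.

    With ``differenced`` both series are generalized-differenced first,
    removing shared trends and autocorrelation before correlating.
    """
    x = np.asarray(disparity, dtype=float)
    y = np.asarray(diversity, dtype=float)
    if differenced:
        x = generalized_differencing(x, times)
        y = generalized_differencing(y, times)
    if coef == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    elif coef == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown coefficient {coef!r}")
    return float(r), float(p)
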