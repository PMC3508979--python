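"""Evaluation and population-comparison statistics.

Parameter recovery is scored by the mean absolute percentage error (MAPE).
Cell populations are compared on the bivariate (count, mean length)
estimates: covariance homogeneity by Box's M, mean differences by pairwise
two-sample Hotelling's T² with balanced subsampling (35 cells per group,
100 repeats) and two-level Bonferroni correction, plus hierarchical
clustering of the T² statistics, PCA summaries of feature tables, and
Pearson correlations (e.g. polymerized tubulin n·mu against total
fluorescence or cytosolic area).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "mape",
    "coefficient_of_variation",
    "polymerized_tubulin",
    "hotelling_t2",
    "box_m_test",
    "PairwiseTestResult",
    "pairwise_compare",
    "cluster_tree",
    "pca_first_two",
    "correlate",
]


def mape(true_vals, est_vals) -> float:
    """Mean absolute percentage error, 100 · mean(|est − true| / |true|)."""
    t = np.asarray(true_vals, dtype=float)
    e = np.asarray(est_vals, dtype=float)
    if t.shape != e.shape:
        raise ValueError("length mismatch")
    if np.any(t == 0):
        raise ValueError("true values must be nonzero")
    return float(100.0 * np.mean(np.abs(e - t) / np.abs(t)))


def coefficient_of_variation(vals) -> float:
    """Sample standard deviation divided by the mean."""
    v = np.asarray(vals, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean")
    return float(v.std(ddof=1) / m) if v.size > 1 else 0.0


def polymerized_tubulin(n_hat: float, mu_hat: float) -> float:
    """Total polymer estimate: number of microtubules times mean length."""
    if n_hat < 0 or mu_hat < 0:
        raise ValueError("inputs must be nonnegative")
    return float(n_hat * mu_hat)


def hotelling_t2(group_a, group_b) -> tuple[float, float]:
    """Two-sample Hotelling's T² with pooled covariance.

    Returns (T², p) with the p-value from the exact F transformation,
    F = T² (n−p−1) / (p (n−2)) on (p, n−p−1) degrees of freedom,
    n = nₐ + n_b.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, p = a.shape
    nb, pb = b.shape
    if p != pb:
        raise ValueError("groups must have the same number of variables")
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 rows")
    diff = a.mean(axis=0) - b.mean(axis=0)
    s_pool = ((na - 1) * np.cov(a, rowvar=False)
              + (nb - 1) * np.cov(b, rowvar=False)) / (na + nb - 2)
    try:
        sol = np.linalg.solve(s_pool, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular pooled covariance") from exc
    t2 = float((na * nb) / (na + nb) * diff @ sol)
    n = na + nb
    f_stat = t2 * (n - p - 1) / (p * (n - 2))
    p_val = float(sps.f.sf(f_stat, p, n - p - 1))
    return t2, p_val


def box_m_test(groups) -> tuple[float, float]:
    """Box's M test of covariance-matrix homogeneity across groups.

    Uses the standard chi-square approximation with Box's scale factor;
    df = (k−1) p (p+1) / 2.
    """
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(mats)
    if k < 2:
        raise ValueError("need at least two groups")
    p = mats[0].shape[1]
    ns = np.array([m.shape[0] for m in mats])
    if np.any(ns < 3):
        raise ValueError("each group needs at least 3 rows")
    covs = [np.cov(m, rowvar=False) for m in mats]
    for c in covs:
        if np.linalg.det(c) <= 0:
            raise np.linalg.LinAlgError("singular group covariance")
    v = ns - 1
    s_pool = sum(vi * c for vi, c in zip(v, covs)) / v.sum()
    m_stat = float(
        v.sum() * np.log(np.linalg.det(s_pool))
        - sum(vi * np.log(np.linalg.det(c)) for vi, c in zip(v, covs))
    )
    c1 = (
        (2 * p**2 + 3 * p - 1)
        / (6.0 * (p + 1) * (k - 1))
        * (np.sum(1.0 / v) - 1.0 / v.sum())
    )
    df = (k - 1) * p * (p + 1) / 2.0
    chi2 = m_stat * (1.0 - c1)
    p_val = float(sps.chi2.sf(chi2, df))
    return m_stat, p_val


@dataclass
class PairwiseTestResult:
    """One pair's subsampled Hotelling test with adjusted p-value."""

    group_a: str
    group_b: str
    t2_statistic: float
    p_adjusted: float
    n_subsample: int
    n_repeats: int


def pairwise_compare(
    table: pd.DataFrame,
    columns: tuple[str, str] = ("n_hat", "mu_hat"),
    group_col: str = "group",
    subsample_n: int = 35,
    repeats: int = 100,
    seed: int = 0,
) -> list[PairwiseTestResult]:
    """All pairwise group comparisons by subsampled Hotelling's T².

    Group sizes are unbalanced, so each repeat draws ``subsample_n`` cells
    without replacement from each group and tests the bivariate means.
    The pair's p-value is the minimum over repeats, Bonferroni-corrected
    by the number of repeats and then family-wise by the number of pairs,
    clipped at 1.  The reported T² is from the repeat attaining the
    minimum.  Per-(pair, repeat) seeds are derived deterministically from
    the master seed with the pair in sorted name order, so (A, B) and
    (B, A) give identical results.
    """
    names = sorted(table[group_col].unique())
    groups = {
        g: table.loc[table[group_col] == g, list(columns)].to_numpy()
        for g in names
    }
    for g, rows in groups.items():
        if len(rows) < subsample_n:
            raise ValueError(f"group {g!r} has fewer than {subsample_n} rows")
    pairs = list(combinations(names, 2))
    results = []
    for pair_idx, (ga, gb) in enumerate(pairs):
        best_p, best_t2 = np.inf, np.nan
        for rep in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, pair_idx, rep])
            )
            sub_a = groups[ga][
                rng.choice(len(groups[ga]), subsample_n, replace=False)
            ]
            sub_b = groups[gb][
                rng.choice(len(groups[gb]), subsample_n, replace=False)
            ]
            t2, p = hotelling_t2(sub_a, sub_b)
            if p < best_p:
                best_p, best_t2 = p, t2
        p_adj = min(1.0, best_p * repeats * len(pairs))
        results.append(
            PairwiseTestResult(ga, gb, best_t2, p_adj, subsample_n, repeats)
        )
    return results


def cluster_tree(
    t2_matrix: np.ndarray, labels: list[str] | None = None, method: str = "average"
) -> str:
    """Hierarchical clustering of groups from a pairwise T² matrix.

    T² is used directly as the dissimilarity (it is not a metric; no
    repair is attempted).  Returns the tree as a Newick string with one
    leaf per group.
    """
    d = np.asarray(t2_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
    k = d.shape[0]
    labels = labels or [f"g{i}" for i in range(k)]
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    tree = hierarchy.to_tree(link)

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({newick(node.left)}:{node.dist:.6g},{newick(node.right)}:{node.dist:.6g})"

    return newick(tree) + ";"


def pca_first_two(features) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of a feature table.

    Returns mean-centred 2D scores and the two explained-variance
    fractions.  Component signs are fixed (the largest-magnitude loading
    is made positive) so runs are reproducible.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if np.count_nonzero(s > s[0] * 1e-12) < 2:
        raise ValueError("feature matrix has rank < 2")
    for i in range(2):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :2] * s[:2]
    var = s**2
    fractions = var[:2] / var.sum()
    return scores, fractions


def correlate(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)
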