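"""Group comparison: Procrustes distances with permutation tests, CVA and
rank tests.

Group differentiation is measured by the partial Procrustes distance between
group mean shapes, with significance from pairwise label permutation (the
two groups' specimens are pooled and relabelled; the statistic is the
distance between the relabelled group means).  The analysis runs on raw
Procrustes coordinates and, in a second track, on non-allometric residual
coordinates.

Canonical variates analysis is an auxiliary ordination: shape data are first
reduced to leading PCs so the within-group covariance is invertible, then
the within^-1 x between eigenproblem gives canonical axes and Mahalanobis
distances.

Rank tests (Kruskal-Wallis with tie correction, plus the mean-rank
multiple-comparison post hoc) support univariate contrasts such as PC
scores across dietary categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .morphospace import pca as _pca
from .procrustes import _center_and_scale, _optimal_rotation

__all__ = [
    "DistanceTable",
    "RankTestResult",
    "group_distance_permutation",
    "cva_scores",
    "kruskal_wallis",
    "kruskal_posthoc",
]


@dataclass
class DistanceTable:
    """Pairwise group Procrustes distances with permutation p-values."""

    labels: list
    distances: np.ndarray  # (g, g) symmetric, zero diagonal
    p_values: np.ndarray   # (g, g) symmetric, NaN diagonal
    n_permutations: int
    seed: int | None
    track: str = "raw"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.labels)), 2):
            rows.append(
                {
                    "group_a": self.labels[i],
                    "group_b": self.labels[j],
                    "procrustes_distance": self.distances[i, j],
                    "p_value": self.p_values[i, j],
                    "track": self.track,
                }
            )
        return pd.DataFrame(rows)


def _mean_shape_distance(flat_a: np.ndarray, flat_b: np.ndarray) -> float:
    """Partial Procrustes distance between two group mean shapes.

    Means of unit-size aligned configurations drift slightly below unit
    size, so each mean is re-standardised (centred, unit centroid size) and
    optimally rotated before taking the root sum of squares.
    """
    a = _center_and_scale(flat_a.reshape(-1, 3))
    b = _center_and_scale(flat_b.reshape(-1, 3))
    aligned = a @ _optimal_rotation(a, b)
    return float(np.sqrt(((aligned - b) ** 2).sum()))


def group_distance_permutation(coordinates: np.ndarray, groups,
                               n_permutations: int = 10000,
                               seed: int | None = None,
                               track: str = "raw") -> DistanceTable:
    """Pairwise group mean-shape distances with permutation p-values.

    ``coordinates`` is the (n, 3k) matrix of flattened aligned coordinates
    (raw or non-allometric).  For each group pair the null reshuffles the
    two groups' labels; p-values use the add-one convention.
    """
    data = np.asarray(coordinates, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    g = len(labels)
    indices = {lab: np.flatnonzero(groups == lab) for lab in labels}
    for lab, idx in indices.items():
        if idx.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 specimens")
    distances = np.zeros((g, g))
    p_values = np.full((g, g), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(g), 2):
        idx_a, idx_b = indices[labels[i]], indices[labels[j]]
        pooled = data[np.concatenate([idx_a, idx_b])]
        n_a = idx_a.size
        n_pool = pooled.shape[0]
        observed = _mean_shape_distance(
            pooled[:n_a].mean(axis=0), pooled[n_a:].mean(axis=0)
        )
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n_pool)
            d = _mean_shape_distance(
                pooled[perm[:n_a]].mean(axis=0), pooled[perm[n_a:]].mean(axis=0)
            )
            if d >= observed - 1e-15:
                count += 1
        distances[i, j] = distances[j, i] = observed
        p_values[i, j] = p_values[j, i] = (count + 1) / (n_permutations + 1)
    return DistanceTable(
        labels=labels,
        distances=distances,
        p_values=p_values,
        n_permutations=n_permutations,
        seed=seed,
        track=track,
    )


def cva_scores(coordinates: np.ndarray, groups,
               n_retained_pcs: int | None = None):
    """Canonical variates analysis on PC-reduced shape data.

    Returns ``(scores, mahalanobis, labels, eigenvalues)``: canonical
    variate scores (n x min(g-1, q)), the pairwise group Mahalanobis
    distance matrix, the group labels in order, and the CVA eigenvalues.
    By default as many leading PCs are retained as explain 95 % of the
    variance, capped at n - g - 1.
    """
    data = np.asarray(coordinates, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    g = len(labels)
    n = data.shape[0]
    if g < 2:
        raise ValueError("need at least 2 groups")
    pca_result = _pca(data)
    if n_retained_pcs is None:
        cum = np.cumsum(pca_result.percent_variance)
        n_retained_pcs = int(np.searchsorted(cum, 95.0) + 1)
        n_retained_pcs = min(n_retained_pcs, n - g - 1)
    if n_retained_pcs < 1 or n - g <= n_retained_pcs:
        raise ValueError(
            f"cannot retain {n_retained_pcs} PCs with n={n} specimens in "
            f"{g} groups"
        )
    reduced = pca_result.scores[:, :n_retained_pcs]
    q = reduced.shape[1]
    grand = reduced.mean(axis=0)
    within = np.zeros((q, q))
    between = np.zeros((q, q))
    means = {}
    for lab in labels:
        sub = reduced[groups == lab]
        means[lab] = sub.mean(axis=0)
        centred = sub - means[lab]
        within += centred.T @ centred
        diff = means[lab] - grand
        between += sub.shape[0] * np.outer(diff, diff)
    within /= n - g
    evals, evecs = np.linalg.eig(np.linalg.solve(within, between))
    order = np.argsort(evals.real)[::-1]
    n_cv = min(g - 1, q)
    evals = evals.real[order][:n_cv]
    axes = evecs.real[:, order][:, :n_cv]
    scores = (reduced - grand) @ axes
    win_inv = np.linalg.inv(within)
    mahal = np.zeros((g, g))
    for i, j in combinations(range(g), 2):
        diff = means[labels[i]] - means[labels[j]]
        mahal[i, j] = mahal[j, i] = float(np.sqrt(diff @ win_inv @ diff))
    return scores, mahal, labels, evals


@dataclass
class RankTestResult:
    chi_square: float
    df: int
    p_value: float
    posthoc: pd.DataFrame | None = None


def kruskal_wallis(values, groups) -> RankTestResult:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square reference)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lab] for lab in labels]
    if np.ptp(values) == 0:
        # identical observations: H is 0 by convention, p is 1
        return RankTestResult(chi_square=0.0, df=len(labels) - 1, p_value=1.0)
    statistic, p_value = stats.kruskal(*samples)
    return RankTestResult(
        chi_square=float(statistic), df=len(labels) - 1, p_value=float(p_value)
    )


def kruskal_posthoc(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise mean-rank comparisons after a Kruskal-Wallis test.

    Uses the normal-approximation critical difference for mean ranks with a
    Bonferroni-style adjustment over the g(g-1)/2 comparisons (the
    convention of the R multiple-comparison rank test): the pair (i, j)
    differs when

        |R_i - R_j| >= z_{1 - alpha / (g (g - 1))} *
                       sqrt(N (N + 1) / 12 * (1/n_i + 1/n_j)).

    Returns one row per pair with observed and critical differences.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n_total = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {lab: ranks[groups == lab].mean() for lab in labels}
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    z_crit = stats.norm.ppf(1 - alpha / (g * (g - 1)))
    rows = []
    for a, b in combinations(labels, 2):
        observed = abs(mean_ranks[a] - mean_ranks[b])
        critical = z_crit * np.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "observed_difference": observed,
                "critical_difference": critical,
                "significant": bool(observed >= critical),
            }
        )
    return pd.DataFrame(rows)
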