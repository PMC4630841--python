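"""Allometry: multivariate regression of shape on log centroid size.

The allometric (ontogenetic) trajectory of a group is the coefficient vector
of the per-coordinate least-squares regression of the flattened Procrustes
coordinates on log centroid size.  Its significance is assessed by permuting
sizes among specimens, using the predicted sum of squares as the statistic.
"Non-allometric" (size-corrected) coordinates are the regression residuals
plus the mean shape.

Trajectories of two groups are compared by the angle between their
allometric vectors, tested against the null that both directions are drawn
independently and uniformly on the unit sphere of the effective shape-space
dimension.  On that sphere the angle between two random directions has
density proportional to sin^(d-2)(theta) on [0, pi]; equivalently
(cos(theta) + 1) / 2 follows a Beta((d-1)/2, (d-1)/2) law, which gives the
analytic p-value P(theta_null <= theta_observed), one-sided toward
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "AngleTestResult",
    "regress_shape_on_size",
    "nonallometric_coordinates",
    "trajectory_angle",
    "angle_similarity_test",
    "ontogenetic_trajectories",
    "shape_space_dimension",
]


@dataclass
class RegressionResult:
    """Multivariate regression of shape on one size predictor."""

    allometric_vector: np.ndarray  # (p,) slope per unit log size
    intercept_shape: np.ndarray    # (p,) fitted shape at log-size 0
    percent_predicted: float       # predicted SS / total SS * 100
    permutation_p: float
    residuals: np.ndarray          # (n, p)
    n_permutations: int
    seed: int | None
    log_sizes: np.ndarray          # (n,) the predictor used
    mean_shape: np.ndarray         # (p,) sample mean of the responses

    @property
    def allometric_direction(self) -> np.ndarray:
        norm = np.linalg.norm(self.allometric_vector)
        if norm == 0:
            raise ValueError("allometric vector is zero")
        return self.allometric_vector / norm


@dataclass
class AngleTestResult:
    angle_degrees: float
    dimension: int
    p_value: float
    method: str
    n_samples: int
    seed: int | None


def _predicted_ss(centred_y: np.ndarray, centred_x: np.ndarray) -> float:
    sxx = float(centred_x @ centred_x)
    xty = centred_x @ centred_y
    return float(xty @ xty) / sxx


def regress_shape_on_size(coordinates: np.ndarray, log_sizes: np.ndarray,
                          n_permutations: int = 10000,
                          seed: int | None = None) -> RegressionResult:
    """Regress each flattened coordinate on the common log-size predictor.

    The permutation test permutes ``log_sizes`` among specimens and uses the
    predicted sum of squares as the statistic; the p-value uses the add-one
    convention (count of permuted >= observed + 1) / (n_permutations + 1),
    so it is never zero.
    """
    data = np.asarray(coordinates, dtype=float)
    x = np.asarray(log_sizes, dtype=float)
    if data.ndim != 2 or data.shape[0] != x.shape[0]:
        raise ValueError("coordinates must be (n, p) with one log size per row")
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("log sizes are constant; allometric regression undefined")
    mean_shape = data.mean(axis=0)
    yc = data - mean_shape
    slope = (xc @ yc) / sxx
    intercept = mean_shape - slope * x.mean()
    fitted_centred = np.outer(xc, slope)
    residuals = yc - fitted_centred
    total_ss = float((yc**2).sum())
    pred_ss = float((fitted_centred**2).sum())
    percent = 100.0 * pred_ss / total_ss if total_ss > 0 else 0.0
    # vectorised permutation null of the predicted SS
    rng = np.random.default_rng(seed)
    perm_x = np.empty((n_permutations, n))
    for i in range(n_permutations):
        perm_x[i] = rng.permutation(xc)
    perm_pred = (perm_x @ yc)  # (P, p)
    perm_ss = (perm_pred**2).sum(axis=1) / sxx
    p_value = (int((perm_ss >= pred_ss - 1e-12 * max(pred_ss, 1.0)).sum()) + 1) / (
        n_permutations + 1
    )
    return RegressionResult(
        allometric_vector=slope,
        intercept_shape=intercept,
        percent_predicted=percent,
        permutation_p=p_value,
        residuals=residuals,
        n_permutations=n_permutations,
        seed=seed,
        log_sizes=x.copy(),
        mean_shape=mean_shape,
    )


def nonallometric_coordinates(result: RegressionResult) -> np.ndarray:
    """Size-corrected coordinates: residuals shifted back to the mean shape."""
    return result.residuals + result.mean_shape


def trajectory_angle(vector_a: np.ndarray, vector_b: np.ndarray) -> float:
    """Angle in degrees between two trajectory vectors, in [0, 180]."""
    a = np.asarray(vector_a, dtype=float).ravel()
    b = np.asarray(vector_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot measure an angle against a zero vector")
    cosine = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _angle_cdf(angle_rad: float, dimension: int) -> float:
    """P(null angle <= angle) for uniform directions in `dimension` dims."""
    half = (dimension - 1) / 2.0
    upper = (np.cos(angle_rad) + 1.0) / 2.0
    return float(stats.beta.sf(upper, half, half))


def angle_similarity_test(vector_a: np.ndarray, vector_b: np.ndarray,
                          dimension: int, method: str = "analytic",
                          n_samples: int = 100000,
                          seed: int | None = None) -> AngleTestResult:
    """Test whether two trajectory directions are more similar than chance.

    The null draws both directions independently and uniformly on the unit
    sphere in ``dimension`` dimensions; the p-value is the null probability
    of an angle at most as large as observed (one-sided toward similarity).
    ``method="analytic"`` evaluates the Beta-law CDF of cos(theta);
    ``method="monte_carlo"`` samples direction pairs and applies the add-one
    convention.
    """
    if dimension < 2:
        raise ValueError("dimension must be at least 2")
    angle_deg = trajectory_angle(vector_a, vector_b)
    angle_rad = np.radians(angle_deg)
    if method == "analytic":
        p_value = max(_angle_cdf(angle_rad, dimension), np.finfo(float).tiny)
        used = 0
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        # rotation invariance: compare one random direction against e1
        draws = rng.standard_normal((n_samples, dimension))
        cosines = draws[:, 0] / np.linalg.norm(draws, axis=1)
        count = int((np.arccos(np.clip(cosines, -1, 1)) <= angle_rad + 1e-12).sum())
        p_value = (count + 1) / (n_samples + 1)
        used = n_samples
    else:
        raise ValueError("method must be 'analytic' or 'monte_carlo'")
    return AngleTestResult(
        angle_degrees=angle_deg,
        dimension=dimension,
        p_value=float(p_value),
        method=method,
        n_samples=used,
        seed=seed,
    )


def shape_space_dimension(n_specimens: int, n_landmarks: int,
                          symmetric: bool = False,
                          n_paired: int | None = None,
                          n_midline: int | None = None) -> int:
    """Effective dimension of the shape tangent space.

    For ordinary 3D Procrustes data the dimension is min(n - 1, 3k - 7)
    (translation 3, scale 1, rotation 3 removed).  For symmetric components
    of a structure with p landmark pairs and m midline landmarks, the
    symmetric subspace has 3p + 2m coordinates; superimposition removes the
    two in-plane translations, the rotation about the symmetry axis and
    scale, leaving 3p + 2m - 4.
    """
    if symmetric:
        if n_paired is None or n_midline is None:
            raise ValueError("symmetric dimension needs pair/midline counts")
        full = 3 * n_paired + 2 * n_midline - 4
    else:
        full = 3 * n_landmarks - 7
    return int(min(n_specimens - 1, full))


def ontogenetic_trajectories(coordinates: np.ndarray, log_sizes: np.ndarray,
                             groups, pairs=None, dimension: int | None = None,
                             n_permutations: int = 10000,
                             angle_method: str = "analytic",
                             seed: int | None = None):
    """Per-group allometric regressions and pairwise trajectory-angle tests.

    ``coordinates`` and ``log_sizes`` come from one joint superimposition;
    groups are fitted separately on that shared shape space.  Returns
    ``(regressions, angle_tests)`` keyed by group label and label pair.
    Each group needs at least 3 specimens spanning a size range.
    """
    data = np.asarray(coordinates, dtype=float)
    x = np.asarray(log_sizes, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # stable order
    if dimension is None:
        dimension = min(data.shape[0] - 1, data.shape[1])
    rng = np.random.default_rng(seed)
    regressions: dict = {}
    for label in labels:
        mask = groups == label
        if int(mask.sum()) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 specimens")
        regressions[label] = regress_shape_on_size(
            data[mask], x[mask], n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
    wanted = list(pairs) if pairs is not None else list(combinations(labels, 2))
    angle_tests: dict = {}
    for a, b in wanted:
        angle_tests[(a, b)] = angle_similarity_test(
            regressions[a].allometric_vector,
            regressions[b].allometric_vector,
            dimension=dimension,
            method=angle_method,
            seed=int(rng.integers(2**31 - 1)),
        )
    return regressions, angle_tests
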