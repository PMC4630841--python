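"""Principal component analysis of shape coordinates and morphospace plots.

PCA is performed on the sample covariance matrix (divisor n - 1) of the
flattened Procrustes coordinates (or symmetric components, or non-allometric
residuals).  Axis signs are fixed by making the largest-magnitude loading of
each axis positive, so scores are deterministic across runs and platforms.

Group scatter is summarised with equal-frequency confidence ellipses: the 2D
group mean and covariance, scaled by the chi-square quantile with 2 degrees
of freedom at the requested coverage level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PCAResult", "pca", "confidence_ellipse", "shape_along_pc", "Ellipse2D",
           "plot_morphospace"]


@dataclass
class PCAResult:
    mean_vector: np.ndarray        # (p,)
    eigenvalues: np.ndarray        # (c,) non-increasing
    percent_variance: np.ndarray   # (c,), sums to 100 over retained axes
    axes: np.ndarray               # (c, p) orthonormal rows
    scores: np.ndarray             # (n, c)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def pca(coordinates: np.ndarray, drop_tol: float = 1e-12) -> PCAResult:
    """Covariance-matrix PCA of an (n, p) data matrix.

    Components with eigenvalue below ``drop_tol`` times the leading
    eigenvalue are discarded as numerically null directions (Procrustes data
    always contain several: the translation, scale and rotation dimensions
    removed by superimposition).
    """
    data = np.asarray(coordinates, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need an (n, p) matrix with n >= 2")
    n = data.shape[0]
    mean = data.mean(axis=0)
    centred = data - mean
    # SVD of the centred data gives the covariance eigenstructure directly
    u, svals, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    if eigenvalues.size and eigenvalues[0] > 0:
        keep = eigenvalues > drop_tol * eigenvalues[0]
    else:
        keep = np.zeros(eigenvalues.size, dtype=bool)
    eigenvalues = eigenvalues[keep]
    axes = vt[keep]
    # deterministic sign: largest-magnitude loading of each axis positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scores = centred @ axes.T
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else eigenvalues * 0.0
    return PCAResult(
        mean_vector=mean,
        eigenvalues=eigenvalues,
        percent_variance=percent,
        axes=axes,
        scores=scores,
    )


@dataclass
class Ellipse2D:
    center: np.ndarray       # (2,)
    semi_axes: np.ndarray    # (2,), major first
    orientation: float       # radians, angle of major axis vs x

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        with np.errstate(divide="ignore", invalid="ignore"):
            value = (local[:, 0] / self.semi_axes[0]) ** 2 + np.where(
                self.semi_axes[1] > 0,
                (local[:, 1] / self.semi_axes[1]) ** 2,
                np.where(np.abs(local[:, 1]) < 1e-12, 0.0, np.inf),
            )
        return value <= 1.0 + 1e-12

    def boundary(self, n_points: int = 100) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n_points)
        local = np.column_stack(
            [self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)]
        )
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + self.center


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> Ellipse2D:
    """Equal-frequency ellipse of 2D scores at the given coverage level.

    The ellipse is the contour of the fitted bivariate normal containing
    probability ``level``: eigen-axes of the 2x2 sample covariance, scaled by
    sqrt(chi2 quantile with 2 df).
    """
    scores = np.asarray(scores_2d, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores_2d must be (n, 2)")
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.sqrt(stats.chi2.ppf(level, df=2))
    semi_axes = scale * np.sqrt(evals)
    orientation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse2D(center=center, semi_axes=semi_axes, orientation=orientation)


def shape_along_pc(pca_result: PCAResult, component: int, score: float) -> np.ndarray:
    """Model shape at a given score along one PC, refolded to (k, 3).

    ``score = 0`` returns the consensus; the extremes of the observed score
    range give the wireframe "extreme shape" models.
    """
    if not 0 <= component < pca_result.n_components:
        raise IndexError(
            f"component {component} out of range "
            f"(0..{pca_result.n_components - 1})"
        )
    flat = pca_result.mean_vector + score * pca_result.axes[component]
    return flat.reshape(-1, 3)


def plot_morphospace(scores: np.ndarray, groups, ax=None, components=(0, 1),
                     level: float = 0.95, percent_variance=None):
    """Scatter plot of two PC axes with per-group confidence ellipses.

    ``groups`` is a sequence of labels, one per row of ``scores``.  Groups
    with fewer than 3 members are drawn without an ellipse.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    groups = np.asarray(groups)
    ci, cj = components
    for label in np.unique(groups):
        mask = groups == label
        pts = scores[mask][:, [ci, cj]]
        handle = ax.scatter(pts[:, 0], pts[:, 1], s=18, alpha=0.75, label=str(label))
        if pts.shape[0] >= 3:
            try:
                ellipse = confidence_ellipse(pts, level=level)
            except np.linalg.LinAlgError:
                continue
            boundary = ellipse.boundary()
            ax.plot(boundary[:, 0], boundary[:, 1], lw=1.0,
                    color=handle.get_facecolor()[0])
    def _axis_label(idx):
        if percent_variance is not None and idx < len(percent_variance):
            return f"PC{idx + 1} ({percent_variance[idx]:.1f}%)"
        return f"PC{idx + 1}"
    ax.set_xlabel(_axis_label(ci))
    ax.set_ylabel(_axis_label(cj))
    ax.axhline(0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(0, color="0.85", lw=0.8, zorder=0)
    ax.legend(fontsize=8, frameon=False)
    return ax
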