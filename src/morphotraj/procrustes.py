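"""Procrustes superimposition and object-symmetry decomposition.

Implements partial Procrustes methods: configurations are centred and scaled
to unit centroid size, and rotations (determinant +1 unless reflection is
explicitly allowed) minimise the residual sum of squares.  Generalized
Procrustes Analysis (GPA) iterates alignment to a running consensus until
the total sum of squares stabilises.

For bilaterally symmetric structures digitized on both sides (object
symmetry), each configuration is superimposed together with its
reflected-and-relabelled copy: the average of the two aligned copies is the
symmetric shape component, the half-difference the asymmetric component.
Downstream analyses of such structures use the symmetric components only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LandmarkDataset
from .templates import LandmarkTemplate

__all__ = [
    "centroid_size",
    "align_to",
    "gpa",
    "gpa_with_object_symmetry",
    "procrustes_distance",
    "reflect_relabel",
    "GPAResult",
    "SymmetryResult",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard geometric size measure for a landmark configuration, in the
    units of the input coordinates.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValueError("config must be a (k, d) array with k >= 1")
    if not np.all(np.isfinite(config)):
        raise ValueError(
            "configuration contains non-finite values; estimate missing "
            "landmarks before computing centroid size"
        )
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def _center_and_scale(config: np.ndarray) -> np.ndarray:
    centred = config - config.mean(axis=0)
    size = np.sqrt((centred**2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centred / size


def _optimal_rotation(config: np.ndarray, reference: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimising ||config @ R - reference||_F (both centred)."""
    u, s, vt = np.linalg.svd(config.T @ reference)
    rotation = u @ vt
    if not allow_reflection and np.linalg.det(rotation) < 0:
        u[:, -1] *= -1
        rotation = u @ vt
    return rotation


def align_to(config: np.ndarray, reference: np.ndarray,
             allow_reflection: bool = False) -> tuple[np.ndarray, float]:
    """Superimpose ``config`` on ``reference`` (both k x d, same k).

    The configuration is centred, scaled to unit centroid size, and rotated
    to minimise the summed squared distance to the centred, unit-size
    reference.  Returns the aligned configuration and the residual sum of
    squares.
    """
    config = np.asarray(config, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if config.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: config {config.shape} vs reference {reference.shape}"
        )
    a = _center_and_scale(config)
    b = _center_and_scale(reference)
    if np.linalg.matrix_rank(a, tol=1e-12) < 2:
        raise ValueError("alignment undefined: configuration has rank < 2")
    aligned = a @ _optimal_rotation(a, b, allow_reflection)
    residual = float(((aligned - b) ** 2).sum())
    return aligned, residual


@dataclass
class GPAResult:
    """Output of generalized Procrustes analysis."""

    consensus: np.ndarray          # (k, 3), unit centroid size
    aligned: np.ndarray            # (n, k, 3), each unit centroid size
    centroid_sizes: np.ndarray     # (n,), sizes of the raw inputs
    log_centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    ss_trace: np.ndarray           # total Procrustes SS per iteration

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (n, 3k) matrix."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


@dataclass
class SymmetryResult:
    """Object-symmetry decomposition of aligned configurations."""

    symmetric: np.ndarray   # (n, k, 3) symmetric components
    asymmetric: np.ndarray  # (n, k, 3) asymmetry deviations
    consensus: np.ndarray   # symmetric mean shape
    reflection_axis: int = 0

    def flattened(self) -> np.ndarray:
        n = self.symmetric.shape[0]
        return self.symmetric.reshape(n, -1)


def _total_ss(aligned: np.ndarray, consensus: np.ndarray) -> float:
    return float(((aligned - consensus[None]) ** 2).sum())


def _gpa_configs(configs: np.ndarray, tol: float, max_iter: int
                 ) -> tuple[np.ndarray, np.ndarray, int, bool, np.ndarray]:
    """GPA on an (n, k, d) stack of raw configurations."""
    n = configs.shape[0]
    scaled = np.stack([_center_and_scale(c) for c in configs])
    consensus = _center_and_scale(scaled[0].copy())
    aligned = scaled.copy()
    trace: list[float] = []
    converged = False
    prev_ss = np.inf
    iteration = 0
    for iteration in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        consensus = _center_and_scale(aligned.mean(axis=0))
        ss = _total_ss(aligned, consensus)
        trace.append(ss)
        if np.isfinite(prev_ss) and prev_ss - ss <= tol * max(prev_ss, 1e-300):
            converged = True
            break
        prev_ss = ss
    return aligned, consensus, iteration, converged, np.asarray(trace)


def gpa(dataset, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Generalized Procrustes analysis of a complete dataset.

    Accepts a :class:`LandmarkDataset` or an ``(n, k, 3)`` array.  All
    configurations are centred and scaled to unit centroid size, then
    iteratively rotated to the consensus (the unit-size mean of the aligned
    configurations) until the relative drop in total Procrustes sum of
    squares is below ``tol``.
    """
    if isinstance(dataset, LandmarkDataset):
        configs = dataset.coordinate_array()
    else:
        configs = np.asarray(dataset, dtype=float)
    if configs.ndim != 3:
        raise ValueError("expected an (n, k, 3) array of configurations")
    if configs.shape[0] < 2:
        raise ValueError("GPA needs at least 2 specimens")
    sizes = np.array([centroid_size(c) for c in configs])
    aligned, consensus, iterations, converged, trace = _gpa_configs(
        configs, tol, max_iter
    )
    if not converged:
        import warnings

        warnings.warn(
            f"GPA did not converge in {iterations} iterations", RuntimeWarning
        )
    return GPAResult(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        log_centroid_sizes=np.log(sizes),
        iterations=iterations,
        converged=converged,
        ss_trace=trace,
    )


def reflect_relabel(config: np.ndarray, template: LandmarkTemplate,
                    axis: int = 0) -> np.ndarray:
    """Mirror a configuration across the plane normal to ``axis`` and swap
    the left/right members of each landmark pair.

    A perfectly symmetric configuration is a fixed point of this map (after
    centring).
    """
    if not template.has_symmetry:
        raise ValueError(
            f"template {template.structure_name} has no left/right pairing"
        )
    out = np.asarray(config, dtype=float).copy()
    out[:, axis] = -out[:, axis]
    for left, right in template.pairs:
        out[[left, right]] = out[[right, left]]
    return out


def gpa_with_object_symmetry(dataset: LandmarkDataset, tol: float = 1e-10,
                             max_iter: int = 100,
                             axis: int = 0) -> tuple[GPAResult, SymmetryResult]:
    """GPA with the reflect-relabel object-symmetry decomposition.

    Each specimen and its reflected-relabelled copy enter a joint GPA over
    2n configurations.  The symmetric component of a specimen is the average
    of its two aligned copies; the asymmetric component the half-difference.
    The returned :class:`GPAResult` describes the joint superimposition of
    the original (unreflected) copies, with the symmetric consensus.
    """
    template = dataset.template
    if not template.has_symmetry:
        raise ValueError(
            f"template {template.structure_name} carries no symmetry "
            "information; use gpa() instead"
        )
    configs = dataset.coordinate_array()
    n = configs.shape[0]
    mirrored = np.stack([reflect_relabel(c, template, axis) for c in configs])
    both = np.concatenate([configs, mirrored])
    aligned, consensus, iterations, converged, trace = _gpa_configs(
        both, tol, max_iter
    )
    originals = aligned[:n]
    reflections = aligned[n:]
    symmetric = (originals + reflections) / 2.0
    asymmetric = (originals - reflections) / 2.0
    sizes = np.array([centroid_size(c) for c in configs])
    gpa_result = GPAResult(
        consensus=consensus,
        aligned=originals,
        centroid_sizes=sizes,
        log_centroid_sizes=np.log(sizes),
        iterations=iterations,
        converged=converged,
        ss_trace=trace,
    )
    sym_result = SymmetryResult(
        symmetric=symmetric,
        asymmetric=asymmetric,
        consensus=consensus,
        reflection_axis=axis,
    )
    return gpa_result, sym_result


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are centred and scaled to unit centroid size; one is rotated
    optimally onto the other; the distance is the square root of the
    residual sum of squares.  Symmetric in its arguments.
    """
    a = _center_and_scale(np.asarray(shape_a, dtype=float))
    b = _center_and_scale(np.asarray(shape_b, dtype=float))
    aligned = a @ _optimal_rotation(a, b)
    return float(np.sqrt(((aligned - b) ** 2).sum()))
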