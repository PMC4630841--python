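"""Missing-landmark estimation by thin-plate-spline interpolation.

Incomplete specimens (common in fossil material) are completed by warping a
complete reference shape onto each specimen's observed landmarks with a 3D
thin-plate spline — the smooth interpolant minimising bending energy — and
reading the missing landmarks off the warped reference.

The 3D kernel is the biharmonic radial function U(r) = r.  The mapping is
exact at the source landmarks, reproduces affine transforms exactly (zero
bending energy), and the non-affine weights satisfy the usual side
conditions (orthogonality to constants and to the source coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LandmarkDataset, SpecimenRecord
from .procrustes import _center_and_scale, _optimal_rotation, gpa

__all__ = ["TPSMapping", "fit_tps", "warp_points", "estimate_missing"]

_MIN_OBSERVED = 5


@dataclass
class TPSMapping:
    """A fitted 3D thin-plate-spline interpolant."""

    source_points: np.ndarray      # (m, 3)
    target_points: np.ndarray      # (m, 3)
    affine_part: np.ndarray        # (4, 3): row 0 translation, rows 1-3 linear
    nonaffine_weights: np.ndarray  # (m, 3)
    kernel: str = "r"

    def __call__(self, query: np.ndarray) -> np.ndarray:
        return warp_points(self, query)

    @property
    def is_affine(self) -> bool:
        return bool(np.allclose(self.nonaffine_weights, 0.0, atol=1e-9))


def _kernel_matrix(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    diff = points_a[:, None, :] - points_b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSMapping:
    """Fit the interpolating 3D thin-plate spline source -> target.

    Requires at least 5 source points not all lying in one plane (the
    affine part alone is otherwise under-determined).  On a near-singular
    system a small ridge (1e-10 x trace) is retried before giving up.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must both be (m, 3)")
    m = source.shape[0]
    if m < _MIN_OBSERVED:
        raise ValueError(f"need at least {_MIN_OBSERVED} points, got {m}")
    centred = source - source.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(centred).max())) < 3:
        raise np.linalg.LinAlgError(
            "source points are coplanar or degenerate; the thin-plate-spline "
            "system is singular"
        )
    kernel = _kernel_matrix(source, source)
    poly = np.hstack([np.ones((m, 1)), source])  # (m, 4)
    system = np.zeros((m + 4, m + 4))
    system[:m, :m] = kernel
    system[:m, m:] = poly
    system[m:, :m] = poly.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = target
    try:
        solution = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(kernel)
        system[:m, :m] += ridge * np.eye(m)
        solution = np.linalg.solve(system, rhs)
    weights = solution[:m]
    affine = solution[m:]
    # exact-interpolation sanity check
    residual = np.abs(kernel @ weights + poly @ affine - target).max()
    scale = max(1.0, np.abs(target).max())
    if residual > 1e-6 * scale:
        raise np.linalg.LinAlgError(
            f"thin-plate-spline system ill-conditioned (residual {residual:.2e})"
        )
    return TPSMapping(
        source_points=source.copy(),
        target_points=target.copy(),
        affine_part=affine,
        nonaffine_weights=weights,
    )


def warp_points(mapping: TPSMapping, query: np.ndarray) -> np.ndarray:
    """Evaluate a fitted spline at arbitrary query points."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    kernel = _kernel_matrix(query, mapping.source_points)
    poly = np.hstack([np.ones((query.shape[0], 1)), query])
    return kernel @ mapping.nonaffine_weights + poly @ mapping.affine_part


def _procrustes_reference(dataset: LandmarkDataset) -> np.ndarray:
    complete = [s.coordinates for s in dataset if s.is_complete]
    if len(complete) == 0:
        raise ValueError(
            "no complete specimen available to build the grand-mean reference"
        )
    if len(complete) == 1:
        return _center_and_scale(complete[0])
    result = gpa(np.stack(complete))
    return result.consensus


def estimate_missing(dataset: LandmarkDataset,
                     reference: np.ndarray | str = "grand_mean_complete"
                     ) -> LandmarkDataset:
    """Complete every incomplete specimen in a dataset.

    For each incomplete specimen the reference (by default the Procrustes
    grand mean of the complete specimens) is superimposed on the specimen's
    observed landmarks — translation, rotation and scale — and a thin-plate
    spline is fitted from the superimposed reference's observed subset to
    the specimen's observed landmarks.  Missing landmarks are placed at the
    warped positions of the corresponding reference landmarks, in the
    specimen's own coordinate frame (the procedure is therefore equivariant
    under rigid motion of the specimen).

    Complete datasets are returned unchanged (same coordinates, fresh
    container).
    """
    if isinstance(reference, str):
        if reference != "grand_mean_complete":
            raise ValueError(
                "reference must be 'grand_mean_complete' or an explicit shape"
            )
        ref_shape = _procrustes_reference(dataset)
    else:
        ref_shape = np.asarray(reference, dtype=float)
        if ref_shape.shape != (dataset.template.n_landmarks, 3):
            raise ValueError("explicit reference shape does not match template")
    completed: list[SpecimenRecord] = []
    n_completed = 0
    for spec in dataset:
        if spec.is_complete:
            completed.append(spec)
            continue
        observed = ~spec.missing_mask
        n_obs = int(observed.sum())
        if n_obs < _MIN_OBSERVED:
            raise ValueError(
                f"specimen {spec.specimen_id!r} has only {n_obs} observed "
                f"landmarks; at least {_MIN_OBSERVED} are required"
            )
        obs_coords = spec.coordinates[observed]
        ref_obs = ref_shape[observed]
        # full Procrustes fit (translation + rotation + scale) of the
        # reference's observed subset onto the specimen's observed landmarks
        ref_centred = ref_obs - ref_obs.mean(axis=0)
        obs_centred = obs_coords - obs_coords.mean(axis=0)
        rotation = _optimal_rotation(ref_centred, obs_centred)
        scale = float(
            np.trace(obs_centred.T @ (ref_centred @ rotation))
            / (ref_centred**2).sum()
        )
        transform = lambda pts: (  # noqa: E731 - local affine map
            (pts - ref_obs.mean(axis=0)) @ rotation * scale
            + obs_coords.mean(axis=0)
        )
        mapping = fit_tps(transform(ref_obs), obs_coords)
        filled = spec.coordinates.copy()
        filled[spec.missing_mask] = warp_points(
            mapping, transform(ref_shape[spec.missing_mask])
        )
        completed.append(
            SpecimenRecord(
                specimen_id=spec.specimen_id,
                species=spec.species,
                age_class=spec.age_class,
                structure=spec.structure,
                coordinates=filled,
                missing_mask=np.zeros(spec.n_landmarks, dtype=bool),
                idas_stage=spec.idas_stage,
                site=spec.site,
            )
        )
        n_completed += 1
    out = LandmarkDataset(
        template=dataset.template,
        specimens=completed,
        provenance=list(dataset.provenance),
    )
    if n_completed:
        out.log(
            f"estimate_missing: completed {n_completed} specimens by TPS "
            "warping of the reference"
        )
    return out
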