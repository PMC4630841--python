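"""Synthetic landmark data with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: species-specific symmetric mean shapes, a shared-direction
ontogenetic allometry with a controllable between-species angle, isotropic
landmark noise applied in shape space (so Procrustes small-variation
assumptions hold by construction), rigid motion and scaling to a drawn
centroid size, and a fraction of missing landmarks in a designated
(fossil-like) species.  Species mean shapes can be evolved by Brownian
motion on a phylogeny so that tip data carry a controllable signal.

Every operation is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LandmarkDataset, SpecimenRecord
from .phylo import PhyloTree, bear_tree
from .procrustes import centroid_size, reflect_relabel
from .templates import LandmarkTemplate, load_template, study_design_table

__all__ = [
    "OntogenySimParams",
    "BMSimParams",
    "make_symmetric_mean",
    "symmetrize",
    "unit_vectors_at_angle",
    "simulate_ontogeny",
    "simulate_bm_tips",
    "bear_like_params",
]

_MIN_OBSERVED = 5  # same floor as missing-landmark estimation


def symmetrize(config: np.ndarray, template: LandmarkTemplate,
               axis: int = 0) -> np.ndarray:
    """Project a configuration onto the object-symmetric subspace.

    Averages the configuration with its reflected-and-relabelled copy;
    midline landmarks land exactly on the symmetry plane, paired landmarks
    become exact mirror images.
    """
    config = np.asarray(config, dtype=float)
    return 0.5 * (config + reflect_relabel(config, template, axis=axis))


def make_symmetric_mean(template: LandmarkTemplate, seed: int) -> np.ndarray:
    """A smooth, non-degenerate mean shape for a template.

    For symmetric templates the result is an exact fixed point of
    reflect-and-relabel.  The configuration is centred at the origin and
    scaled to unit centroid size.
    """
    rng = np.random.default_rng(seed)
    k = template.n_landmarks
    # low-frequency coordinates: smooth random mixture of a few cosine modes
    t = np.linspace(0.0, 1.0, k, endpoint=False)
    config = np.empty((k, 3))
    for d in range(3):
        coeffs = rng.normal(size=4)
        config[:, d] = sum(
            c * np.cos(2 * np.pi * (m + 1) * t + rng.uniform(0, 2 * np.pi))
            for m, c in enumerate(coeffs)
        )
    config += 0.15 * rng.normal(size=(k, 3))  # break accidental degeneracy
    if template.has_symmetry:
        config = symmetrize(config, template)
    config -= config.mean(axis=0)
    size = centroid_size(config)
    if size == 0:
        raise RuntimeError("degenerate random configuration (zero size)")
    return config / size


def unit_vectors_at_angle(dim: int, angle_degrees: float,
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors in R^dim separated by exactly ``angle_degrees``."""
    if dim < 2:
        raise ValueError("dim must be at least 2")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(dim)
    a /= np.linalg.norm(a)
    b = rng.standard_normal(dim)
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    theta = np.radians(angle_degrees)
    return a, np.cos(theta) * a + np.sin(theta) * b


def project_to_horizontal(direction: np.ndarray, mean: np.ndarray,
                          template: LandmarkTemplate | None = None) -> np.ndarray:
    """Project a flattened direction into the horizontal tangent space at
    ``mean``.

    The horizontal space at a unit-size, centred mean shape excludes the
    directions removed by Procrustes superimposition: translations (rows
    centred), uniform scaling (orthogonal to ``mean`` itself) and the three
    infinitesimal rotations (``mean @ A`` for antisymmetric ``A``).  For a
    symmetric template the direction is first projected onto the
    object-symmetric subspace.  Returns a unit vector.

    Allometric directions built this way keep noiseless simulated
    trajectories exactly recoverable by the regression stage: Procrustes
    alignment of specimens generated along such a direction introduces no
    rotational cross-talk.
    """
    k = mean.shape[0]
    folded = np.asarray(direction, dtype=float).reshape(k, 3).copy()
    if template is not None and template.has_symmetry:
        folded = symmetrize(folded, template)
    folded -= folded.mean(axis=0)
    flat = folded.ravel()
    mean_flat = np.asarray(mean, dtype=float).ravel()
    basis = [mean_flat / np.linalg.norm(mean_flat)]
    generators = (
        np.array([[0.0, 1, 0], [-1, 0, 0], [0, 0, 0]]),
        np.array([[0.0, 0, 1], [0, 0, 0], [-1, 0, 0]]),
        np.array([[0.0, 0, 0], [0, 0, 1], [0, -1, 0]]),
    )
    for gen in generators:
        vec = (np.asarray(mean) @ gen).ravel()
        for prev in basis:
            vec = vec - (vec @ prev) * prev
        norm = np.linalg.norm(vec)
        if norm > 1e-12:
            basis.append(vec / norm)
    for prev in basis:
        flat = flat - (flat @ prev) * prev
    norm = np.linalg.norm(flat)
    if norm < 1e-12:
        raise ValueError("direction lies entirely in the removed subspace")
    return flat / norm


@dataclass
class OntogenySimParams:
    """Parameters of the ontogenetic-allometry generator.

    ``species_means`` maps species -> (k, 3) base shape (unit centroid
    size); ``allometric_vectors`` maps species -> unit direction in
    flattened coordinate space; ``size_ranges`` maps (species, age_class)
    -> (min, max) centroid size in mm and ``n_per_group`` the count for the
    same keys.  ``allometry_scale`` converts one unit of log centroid size
    into Procrustes-scale shape displacement along the species direction.
    """

    template: LandmarkTemplate
    species_means: dict
    allometric_vectors: dict
    size_ranges: dict
    n_per_group: dict
    allometry_scale: float = 0.15
    noise_sd: float = 0.002
    asymmetry_sd: float = 0.0
    missing_fraction: float = 0.0
    missing_species: str | None = None
    noise_after_motion: bool = False
    rigid_motion: bool = True
    size_sampling: str = "loguniform"  # or "grid": evenly spaced log sizes
    structure: str = "cranium"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.asymmetry_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        k = self.template.n_landmarks
        for species, vec in self.allometric_vectors.items():
            vec = np.asarray(vec, dtype=float).ravel()
            if vec.size != 3 * k:
                raise ValueError(
                    f"allometric vector for {species!r} has length {vec.size}, "
                    f"expected {3 * k}"
                )
            norm = np.linalg.norm(vec)
            if not np.isclose(norm, 1.0, atol=1e-8):
                raise ValueError(
                    f"allometric vector for {species!r} must have unit norm"
                )
        for key, (lo, hi) in self.size_ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate size range for {key}: ({lo}, {hi})")
        if self.size_sampling not in ("loguniform", "grid"):
            raise ValueError("size_sampling must be 'loguniform' or 'grid'")


@dataclass
class BMSimParams:
    """Brownian-motion simulation on a tree: variance ``rate`` per unit
    branch length, starting from ``root_state``."""

    tree: PhyloTree
    rate: float
    root_state: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        self.root_state = np.atleast_1d(np.asarray(self.root_state, dtype=float))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _age_threshold(size_ranges: dict, species: str) -> float | None:
    """Size cut between juvenile and adult ranges, None if one class only."""
    juv = size_ranges.get((species, "juvenile"))
    adult = size_ranges.get((species, "adult"))
    if juv is None or adult is None:
        return None
    return 0.5 * (juv[1] + adult[0])


def simulate_ontogeny(params: OntogenySimParams) -> LandmarkDataset:
    """Generate a landmark dataset under the allometric ground-truth model.

    Each specimen's shape is
    ``mean_species + allometry_scale * vec_species * (log CS - log CS_ref)``
    plus isotropic noise, rigidly rotated and translated at random and
    scaled to its drawn centroid size.  ``log CS_ref`` is the species
    midpoint of the simulated log-size range, so shapes at mid-size equal
    the species mean.  Centroid sizes are drawn log-uniformly within the
    group's range.  Age classes are assigned from size against the midpoint
    between the juvenile and adult ranges (ground truth by construction).
    """
    rng = np.random.default_rng(params.seed)
    template = params.template
    k = template.n_landmarks
    specimens: list[SpecimenRecord] = []
    counter = 1
    for (species, age_class), n in sorted(params.n_per_group.items()):
        if n <= 0:
            continue
        mean = np.asarray(params.species_means[species], dtype=float)
        vec = np.asarray(params.allometric_vectors[species], dtype=float).reshape(k, 3)
        lo, hi = params.size_ranges[(species, age_class)]
        log_lo, log_hi = np.log(lo), np.log(hi)
        ref_log = _species_reference_log_size(params, species)
        threshold = _age_threshold(params.size_ranges, species)
        if params.size_sampling == "grid":
            # evenly spaced log sizes, symmetric about the range midpoint
            log_size_draws = np.linspace(log_lo, log_hi, n) if n > 1 else \
                np.array([(log_lo + log_hi) / 2.0])
        else:
            log_size_draws = rng.uniform(log_lo, log_hi, size=n)
        for log_size in log_size_draws:
            size = float(np.exp(log_size))
            shape = mean + params.allometry_scale * vec * (log_size - ref_log)
            if params.noise_sd > 0 and not params.noise_after_motion:
                shape = shape + rng.normal(scale=params.noise_sd, size=(k, 3))
            if params.asymmetry_sd > 0 and template.has_symmetry:
                side_noise = rng.normal(scale=params.asymmetry_sd, size=(k, 3))
                shape = shape + (side_noise - reflect_relabel(
                    side_noise, template)) / 2.0
            shape = shape - shape.mean(axis=0)
            shape = shape / centroid_size(shape) * size
            if params.rigid_motion:
                rotation = _random_rotation(rng)
                translation = rng.uniform(-100.0, 100.0, size=3)
                coords = shape @ rotation.T + translation
            else:
                coords = shape
            if params.noise_sd > 0 and params.noise_after_motion:
                coords = coords + rng.normal(
                    scale=params.noise_sd * size, size=(k, 3))
            mask = np.zeros(k, dtype=bool)
            if (params.missing_fraction > 0
                    and species == params.missing_species):
                mask = rng.random(k) < params.missing_fraction
                while k - int(mask.sum()) < _MIN_OBSERVED:
                    mask = rng.random(k) < params.missing_fraction
                coords = coords.copy()
                coords[mask] = np.nan
            assigned = age_class
            if threshold is not None:
                assigned = "juvenile" if size < threshold else "adult"
            specimens.append(
                SpecimenRecord(
                    specimen_id=f"{species}_{age_class}_{counter:04d}",
                    species=species,
                    age_class=assigned,
                    structure=params.structure,
                    coordinates=np.where(mask[:, None], 0.0, coords),
                    missing_mask=mask,
                )
            )
            counter += 1
    dataset = LandmarkDataset(template=template, specimens=specimens)
    dataset.log(
        f"simulate_ontogeny: {len(specimens)} specimens, seed={params.seed}, "
        f"noise_sd={params.noise_sd}, allometry_scale={params.allometry_scale}"
    )
    return dataset


def _species_reference_log_size(params: OntogenySimParams, species: str) -> float:
    logs = [np.log(lo) for (sp, _), (lo, hi) in params.size_ranges.items()
            if sp == species]
    logs += [np.log(hi) for (sp, _), (lo, hi) in params.size_ranges.items()
             if sp == species]
    return float((min(logs) + max(logs)) / 2.0)


def simulate_bm_tips(params: BMSimParams) -> dict:
    """Multivariate Brownian motion along a tree, returning tip values.

    Each trait dimension evolves independently with variance
    ``rate * branch_length`` per branch.  Returns ``{tip_label: vector}``.
    """
    rng = np.random.default_rng(params.seed)
    tree = params.tree
    q = params.root_state.size
    lengths = tree.branch_lengths.copy()
    lengths[0] = 0.0
    if np.isnan(lengths).any():
        raise ValueError("Brownian simulation requires a length on every branch")
    values = np.zeros((tree.n_nodes, q))
    values[0] = params.root_state
    for node in range(1, tree.n_nodes):  # preorder: parent precedes child
        step_sd = np.sqrt(params.rate * lengths[node])
        values[node] = values[tree.parent[node]] + rng.normal(
            scale=step_sd, size=q) if step_sd > 0 else values[tree.parent[node]]
    return {
        label: values[tid].copy()
        for label, tid in zip(tree.tip_labels, tree.tip_ids)
    }


# --- the study-shaped default scenario -------------------------------------

_SIZE_RANGES_MM = {
    "cranium": {
        ("arctos", "adult"): (330.0, 480.0),
        ("arctos", "juvenile"): (140.0, 300.0),
        ("americanus", "adult"): (260.0, 360.0),
        ("maritimus", "adult"): (330.0, 450.0),
        ("spelaeus", "adult"): (400.0, 560.0),
        ("spelaeus", "juvenile"): (160.0, 360.0),
    },
    "mandible": {
        ("arctos", "adult"): (220.0, 330.0),
        ("arctos", "juvenile"): (90.0, 200.0),
        ("americanus", "adult"): (170.0, 240.0),
        ("maritimus", "adult"): (220.0, 310.0),
        ("spelaeus", "adult"): (270.0, 380.0),
        ("spelaeus", "juvenile"): (100.0, 240.0),
    },
}

_BEAR_SPECIES = ("americanus", "arctos", "maritimus", "spelaeus")


def bear_like_params(structure: str = "cranium", seed: int = 0,
                     trajectory_angle_degrees: float = 40.0,
                     species_effect_scale: float = 0.05,
                     noise_sd: float = 0.002,
                     allometry_scale: float = 0.15,
                     missing_fraction: float = 0.1,
                     phylo_signal: bool = False,
                     null_model: bool = False) -> OntogenySimParams:
    """The study-shaped scenario: four species with the published group sizes.

    Species mean shapes are the base shape plus per-species offsets of
    Procrustes magnitude ``species_effect_scale``; by default offsets are
    independent draws (no phylogenetic structure), with ``phylo_signal``
    they are evolved by Brownian motion on the study topology.  All species
    share one ontogenetic direction except the designated fossil species,
    whose trajectory sits at ``trajectory_angle_degrees`` to it.  A fraction
    of landmarks is masked as missing in the fossil species (cranium only).

    ``null_model`` zeroes every effect (equal means, no allometry) for
    calibration runs.
    """
    template = load_template(
        "cranium36" if structure == "cranium" else "mandible9")
    k = template.n_landmarks
    rng = np.random.default_rng(seed)
    base = make_symmetric_mean(template, seed=int(rng.integers(2**31 - 1)))

    design = study_design_table()
    design = design[design["structure"] == structure]
    n_per_group = {
        (row.species, row.age_class): int(row.n)
        for row in design.itertuples()
    }

    def _shape_direction(raw: np.ndarray) -> np.ndarray:
        """Symmetrize (when applicable) and normalise a flattened direction."""
        folded = raw.reshape(k, 3)
        if template.has_symmetry:
            folded = symmetrize(folded, template)
        folded = folded - folded.mean(axis=0)
        flat = folded.ravel()
        return flat / np.linalg.norm(flat)

    species_means = {}
    if null_model:
        for species in _BEAR_SPECIES:
            species_means[species] = base.copy()
    elif phylo_signal:
        tree = bear_tree("unit_lengths")
        bm = simulate_bm_tips(BMSimParams(
            tree=tree, rate=species_effect_scale**2 / 3.0,
            root_state=np.zeros(3 * k),
            seed=int(rng.integers(2**31 - 1)),
        ))
        for species in _BEAR_SPECIES:
            offset = _shape_direction(bm[species]) * np.linalg.norm(bm[species])
            species_means[species] = base + offset.reshape(k, 3)
    else:
        for species in _BEAR_SPECIES:
            raw = rng.standard_normal(3 * k)
            offset = _shape_direction(raw) * species_effect_scale
            species_means[species] = base + offset.reshape(k, 3)

    shared_raw, fossil_raw = unit_vectors_at_angle(
        3 * k, trajectory_angle_degrees, seed=int(rng.integers(2**31 - 1)))
    shared = project_to_horizontal(shared_raw, base, template)
    # rebuild the fossil direction at the requested angle inside the
    # horizontal (and, for the cranium, symmetric) subspace
    fossil = project_to_horizontal(fossil_raw, base, template)
    fossil = fossil - (fossil @ shared) * shared
    norm = np.linalg.norm(fossil)
    if norm < 1e-12:
        raise RuntimeError("could not build an independent fossil direction")
    fossil /= norm
    theta = np.radians(trajectory_angle_degrees)
    fossil = np.cos(theta) * shared + np.sin(theta) * fossil
    allometric_vectors = {
        species: (fossil if species == "spelaeus" else shared)
        for species in _BEAR_SPECIES
    }

    return OntogenySimParams(
        template=template,
        species_means=species_means,
        allometric_vectors=allometric_vectors,
        size_ranges=dict(_SIZE_RANGES_MM[structure]),
        n_per_group=n_per_group,
        allometry_scale=0.0 if null_model else allometry_scale,
        noise_sd=noise_sd,
        missing_fraction=(
            missing_fraction if structure == "cranium" and not null_model
            else 0.0),
        missing_species="spelaeus",
        structure=structure,
        seed=int(rng.integers(2**31 - 1)),
    )
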