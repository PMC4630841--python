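"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from morphotraj.dataset import LandmarkDataset, SpecimenRecord
from morphotraj.templates import load_template


@pytest.fixture(scope="session")
def cranium_template():
    return load_template("cranium36")


@pytest.fixture(scope="session")
def mandible_template():
    return load_template("mandible9")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31 - 1))).as_matrix()


def make_dataset(template, coords_stack, species="arctos", age="adult"):
    """Wrap an (n, k, 3) stack into a LandmarkDataset."""
    specimens = [
        SpecimenRecord(
            specimen_id=f"s{i:03d}", species=species, age_class=age,
            structure=template.structure_name, coordinates=c)
        for i, c in enumerate(coords_stack)
    ]
    return LandmarkDataset(template=template, specimens=specimens)


def brute_force_procrustes_distance(shape_a, shape_b, n_grid=24) -> float:
    """Independent oracle: minimise the superimposition residual over a
    coarse rotation grid, then polish with Nelder-Mead on Euler angles."""
    def standardise(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())

    a = standardise(np.asarray(shape_a, float))
    b = standardise(np.asarray(shape_b, float))

    def residual(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return ((a @ rot - b) ** 2).sum()

    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    best, best_angles = np.inf, None
    for az in grid:
        for ay in np.linspace(-np.pi / 2, np.pi / 2, n_grid // 2):
            for ax in grid:
                value = residual((az, ay, ax))
                if value < best:
                    best, best_angles = value, (az, ay, ax)
    polished = minimize(residual, best_angles, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-14,
                                 "maxiter": 2000})
    return float(np.sqrt(min(best, polished.fun)))
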