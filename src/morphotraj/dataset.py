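"""Specimen records and landmark datasets.

The central container is :class:`LandmarkDataset`: an ordered collection of
:class:`SpecimenRecord` objects sharing one :class:`LandmarkTemplate`.
Coordinates are stored in millimetres as digitized; missing landmarks are an
explicit boolean mask, never a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .templates import LandmarkTemplate

__all__ = ["SpecimenRecord", "LandmarkDataset", "AGE_CLASSES"]

AGE_CLASSES = ("juvenile", "adult")

# Dental-eruption stages: 1-2 permanent dentition incomplete, 3-5 complete.
_IDAS_TO_AGE_CLASS = {1: "juvenile", 2: "juvenile", 3: "adult", 4: "adult", 5: "adult"}


@dataclass
class SpecimenRecord:
    """One digitized specimen: coordinates, missing mask and metadata."""

    specimen_id: str
    species: str
    age_class: str
    structure: str
    coordinates: np.ndarray  # (k, 3), mm
    missing_mask: np.ndarray | None = None  # (k,) bool, True = unobserved
    idas_stage: int | None = None
    site: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(
                f"coordinates must be (k, 3); got {self.coordinates.shape}"
            )
        k = self.coordinates.shape[0]
        if self.missing_mask is None:
            self.missing_mask = np.zeros(k, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (k,):
                raise ValueError("missing_mask must have one entry per landmark")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class must be one of {AGE_CLASSES}")
        if self.idas_stage is not None:
            if self.idas_stage not in _IDAS_TO_AGE_CLASS:
                raise ValueError("idas_stage must be in 1..5")
            if _IDAS_TO_AGE_CLASS[self.idas_stage] != self.age_class:
                raise ValueError(
                    f"age_class {self.age_class!r} inconsistent with "
                    f"idas_stage {self.idas_stage}"
                )
        if not np.all(np.isfinite(self.coordinates[~self.missing_mask])):
            raise ValueError(
                f"specimen {self.specimen_id!r}: non-finite coordinates at "
                "observed landmarks"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing_mask.any())


@dataclass
class LandmarkDataset:
    """Ordered specimens sharing one landmark template."""

    template: LandmarkTemplate
    specimens: list[SpecimenRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        k = self.template.n_landmarks
        ids = set()
        for spec in self.specimens:
            if spec.n_landmarks != k:
                raise ValueError(
                    f"specimen {spec.specimen_id!r} has {spec.n_landmarks} "
                    f"landmarks, template {self.template.structure_name} has {k}"
                )
            if spec.specimen_id in ids:
                raise ValueError(f"duplicate specimen_id {spec.specimen_id!r}")
            ids.add(spec.specimen_id)

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    def __getitem__(self, i: int) -> SpecimenRecord:
        return self.specimens[i]

    @property
    def is_complete(self) -> bool:
        return all(s.is_complete for s in self.specimens)

    def coordinate_array(self) -> np.ndarray:
        """Stack coordinates into an ``(n, k, 3)`` array (complete data only)."""
        if not self.is_complete:
            raise ValueError(
                "dataset has missing landmarks; run estimate_missing first"
            )
        return np.stack([s.coordinates for s in self.specimens])

    def metadata(self):
        """Per-specimen metadata as a DataFrame (specimen order preserved)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen_id": [s.specimen_id for s in self.specimens],
                "species": [s.species for s in self.specimens],
                "age_class": [s.age_class for s in self.specimens],
                "structure": [s.structure for s in self.specimens],
            }
        )

    def subset(self, indices) -> "LandmarkDataset":
        return LandmarkDataset(
            template=self.template,
            specimens=[self.specimens[i] for i in indices],
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)


def age_class_from_idas(stage: int) -> str:
    """Map a dental-eruption stage (1-5) to juvenile/adult."""
    return _IDAS_TO_AGE_CLASS[stage]
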