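"""Landmark templates and the packaged study design.

A :class:`LandmarkTemplate` records, for one skeletal structure, the ordered
landmark names, which landmarks form bilateral (left/right) pairs, and which
lie on the midsagittal plane.  Two templates are packaged:

``cranium36``
    36 cranial landmarks digitized on both sides of the skull: 14 bilateral
    pairs plus 8 unpaired midline landmarks.  This template supports the
    object-symmetry decomposition (reflect, relabel, average).

``mandible9``
    9 landmarks digitized on one hemimandible only; no symmetry structure.

Indices are 0-based throughout the Python API.  File formats and the
documentation of individual landmarks use the conventional 1-based numbering;
every function that touches files says which convention it uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "LandmarkTemplate",
    "load_template",
    "study_design_table",
    "TEMPLATE_NAMES",
]


@dataclass(frozen=True)
class LandmarkTemplate:
    """Names, bilateral pairing and midline membership for a structure.

    Parameters
    ----------
    structure_name
        Short label, e.g. ``"cranium36"``.
    landmark_names
        Ordered landmark descriptions; ``len(landmark_names)`` is the
        landmark count ``k``.
    pairs
        ``(left, right)`` 0-based index pairs of bilaterally homologous
        landmarks.  Lower index is the left-side member by convention.
    midline
        0-based indices of landmarks on the midsagittal plane.
    dimension
        Coordinate dimension; always 3 here.
    """

    structure_name: str
    landmark_names: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()
    dimension: int = 3

    def __post_init__(self) -> None:
        k = self.n_landmarks
        seen: set[int] = set()
        for left, right in self.pairs:
            if not (0 <= left < k and 0 <= right < k) or left == right:
                raise ValueError(f"invalid pair ({left}, {right}) for k={k}")
            if left in seen or right in seen:
                raise ValueError(f"landmark appears in more than one pair: ({left}, {right})")
            seen.update((left, right))
        for m in self.midline:
            if not 0 <= m < k:
                raise ValueError(f"midline index {m} out of range for k={k}")
            if m in seen:
                raise ValueError(f"landmark {m} is both paired and midline")
            seen.add(m)
        if self.has_symmetry and len(seen) != k:
            missing = sorted(set(range(k)) - seen)
            raise ValueError(
                f"symmetric template must partition all landmarks into pairs/midline; "
                f"unassigned: {missing}"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    @property
    def has_symmetry(self) -> bool:
        """True when the template carries object-symmetry structure."""
        return len(self.pairs) > 0


_CRANIUM_NAMES = (
    "Anterior point of the interpremaxillary suture at the alveolar margin of the incisors",
    "Anterior point of the premaxillo-maxillary suture (left)",
    "Anterior point of the premaxillo-maxillary suture (right)",
    "Anterior point of the internasal suture",
    "Intersection of internasal and interfrontal sutures",
    "Dorsal point of the lacrimal bone (left)",
    "Dorsal point of the lacrimal bone (right)",
    "Dorsal tip of the frontal process at the zygomatic arch (left)",
    "Dorsal tip of the frontal process at the zygomatic arch (right)",
    "Tip of the post-orbital process (left)",
    "Tip of the post-orbital process (right)",
    "Intersection of the interparietal and interfrontal sutures",
    "Posterior point of the external auditory meatus (left)",
    "Posterior point of the external auditory meatus (right)",
    "Intersection of parietal, squamosal, and supraoccipital bones (left)",
    "Intersection of parietal, squamosal, and supraoccipital bones (right)",
    "Distal point of the external occipital protuberance",
    "Posterior point of the canine alveolus (left)",
    "Posterior point of the canine alveolus (right)",
    "Posterior point of the tooth row at the alveolar margin (left)",
    "Posterior point of the tooth row at the alveolar margin (right)",
    "Posterior point of maximum concavity on the palatine",
    "Ventral point of the jugo-maxillary suture (left)",
    "Ventral point of the jugo-maxillary suture (right)",
    "Ventral point of the jugo-squamosal suture (left)",
    "Ventral point of the jugo-squamosal suture (right)",
    "Intersection of basioccipital, basisphenoid, and auditory bulla (left)",
    "Intersection of basioccipital, basisphenoid, and auditory bulla (right)",
    "Tip of the mastoid process (left)",
    "Tip of the mastoid process (right)",
    "Ventral tip of the postglenoid process (left)",
    "Ventral tip of the postglenoid process (right)",
    "Lateral point of the occipital condyle (left)",
    "Lateral point of the occipital condyle (right)",
    "Antero-ventral point of the foramen magnum",
    "Postero-dorsal point of the foramen magnum",
)

# 1-based pairs 2/3, 6/7, 8/9, 10/11, 13/14, 15/16, 18/19, 20/21, 23/24,
# 25/26, 27/28, 29/30, 31/32, 33/34; midline 1, 4, 5, 12, 17, 22, 35, 36.
_CRANIUM_PAIRS_1B = (
    (2, 3), (6, 7), (8, 9), (10, 11), (13, 14), (15, 16), (18, 19),
    (20, 21), (23, 24), (25, 26), (27, 28), (29, 30), (31, 32), (33, 34),
)
_CRANIUM_MIDLINE_1B = (1, 4, 5, 12, 17, 22, 35, 36)

_MANDIBLE_NAMES = (
    "Antero-ventral point of the mandibular symphysis at the incisor alveolar margin",
    "Postero-dorsal border of the canine alveolus",
    "Anterior point of the alveolar margin of p4",
    "Posterior point of the alveolar margin of the tooth row",
    "Posterior edge of the coronoid process",
    "Lateral edge of the articular surface of the condyloid process",
    "Medial edge of the articular surface of the condyloid process",
    "Tip of the angular process",
    "Ventral point of the symphyseal region",
)

_TEMPLATES = {
    "cranium36": LandmarkTemplate(
        structure_name="cranium36",
        landmark_names=_CRANIUM_NAMES,
        pairs=tuple((a - 1, b - 1) for a, b in _CRANIUM_PAIRS_1B),
        midline=tuple(m - 1 for m in _CRANIUM_MIDLINE_1B),
    ),
    "mandible9": LandmarkTemplate(
        structure_name="mandible9",
        landmark_names=_MANDIBLE_NAMES,
    ),
}

TEMPLATE_NAMES = tuple(sorted(_TEMPLATES))


def load_template(name: str) -> LandmarkTemplate:
    """Return a packaged landmark template by name.

    Raises
    ------
    KeyError
        If ``name`` is not one of :data:`TEMPLATE_NAMES`.
    """
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise KeyError(
            f"unknown template {name!r}; available: {', '.join(TEMPLATE_NAMES)}"
        ) from None


# Specimen counts of the four-species bear study design (per species,
# structure and age class) that the synthetic scenarios emulate.
_STUDY_DESIGN_ROWS = [
    ("arctos", "cranium", "adult", 56),
    ("arctos", "cranium", "juvenile", 27),
    ("americanus", "cranium", "adult", 28),
    ("maritimus", "cranium", "adult", 42),
    ("spelaeus", "cranium", "adult", 97),
    ("spelaeus", "cranium", "juvenile", 3),
    ("arctos", "mandible", "adult", 56),
    ("arctos", "mandible", "juvenile", 21),
    ("americanus", "mandible", "adult", 28),
    ("maritimus", "mandible", "adult", 43),
    ("spelaeus", "mandible", "adult", 31),
    ("spelaeus", "mandible", "juvenile", 4),
]


def study_design_table() -> pd.DataFrame:
    """Specimen counts of the emulated study design.

    Returns a DataFrame with columns ``species``, ``structure``,
    ``age_class``, ``n``.  Totals: 253 crania, 183 mandibles.
    """
    return pd.DataFrame(
        _STUDY_DESIGN_ROWS, columns=["species", "structure", "age_class", "n"]
    )
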