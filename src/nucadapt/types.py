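"""Core data types shared across the pipeline.

The atomic ground-truth unit is a point annotation: a nucleus center plus one
of three classes used for Ki-67 labeling-index assessment — immunopositive
tumor (IPT, DAB-brown), immunonegative tumor (INT, hematoxylin-blue) and
nontumor (NT) nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed class order; also the channel order of every output map.
CLASSES: tuple[str, ...] = ("IPT", "INT", "NT")

CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class PointAnnotation:
    """A single annotated nucleus center.

    Coordinates are 0-based pixel indices: ``row`` from the top edge,
    ``col`` from the left edge.
    """

    row: int
    col: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_INDEX:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if self.row < 0 or self.col < 0:
            raise ValueError("annotation coordinates must be nonnegative")


@dataclass
class AnnotatedImage:
    """An RGB tile plus its point annotations and a case identifier.

    ``pixels`` is an H×W×3 float array with intensities in [0, 1]. All
    images of one case share ``case_id``; splits are made at case level.
    """

    pixels: np.ndarray
    annotations: list[PointAnnotation]
    case_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise ValueError("images must be at least 64×64")
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        for a in self.annotations:
            if not (0 <= a.row < h and 0 <= a.col < w):
                raise ValueError(f"annotation {a} outside {h}×{w} image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class Detection:
    """A predicted nucleus: peak position, class label and response score."""

    row: int
    col: int
    label: str
    score: float

    def __post_init__(self) -> None:
        if self.label not in CLASS_INDEX:
            raise ValueError(f"label must be one of {CLASSES}")
        if self.score <= 0:
            raise ValueError("detection score must be positive")


def validate_output_map(values: np.ndarray) -> np.ndarray:
    """Check an H×W×3 nonnegative response map and return it as float32."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 3 or values.shape[2] != 3:
        raise ValueError("output map must be H×W×3")
    if np.any(values < 0):
        raise ValueError("output map values must be nonnegative")
    return values
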