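"""Shared domain types.

Conventions used throughout the package:

* coordinates are 0-based ``(x, y) = (column, row)`` with the origin at the
  top-left corner; rasters are numpy arrays indexed ``[row, column]``;
* regions are half-open: a region with origin ``(x, y)`` and size ``(w, h)``
  covers columns ``x .. x+w-1`` and rows ``y .. y+h-1``;
* pixel spacing is isotropic and expressed in micrometres (µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Sampling-mask label codes.  The four annotation classes rasterize to
# EDGE/ARTIFACTS/BACKGROUND/TISSUE; margin labels are added afterwards.
EDGE = 1
ARTIFACTS = 2
BACKGROUND = 3
EXTERNAL_MARGIN = 4
INTERNAL_MARGIN = 5
TISSUE = 6

#: labels that count as tissue when a six-label sampling mask is binarized
TISSUE_LABELS = frozenset({INTERNAL_MARGIN, TISSUE})
#: labels that count as non-tissue
NON_TISSUE_LABELS = frozenset({EDGE, ARTIFACTS, BACKGROUND, EXTERNAL_MARGIN})

LABEL_NAMES = {
    EDGE: "edge",
    ARTIFACTS: "artifacts",
    BACKGROUND: "background",
    EXTERNAL_MARGIN: "external_margin",
    INTERNAL_MARGIN: "internal_margin",
    TISSUE: "tissue",
}

#: annotation classes, in rasterization paint order (later wins), except that
#: explicitly annotated background (tissue holes) is painted last of all.
ANNOTATION_CLASSES = ("background", "edge", "inner_artifact", "tissue")


@dataclass(frozen=True)
class LevelRef:
    """A resolved pyramid level: its index and pixel spacing in µm."""

    level_index: int
    spacing: float

    def __post_init__(self):
        if self.level_index < 0:
            raise ValueError("level_index must be >= 0")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")


@dataclass
class BinaryMask:
    """A tissue (1) / non-tissue (0) raster at a known pixel spacing."""

    data: np.ndarray
    spacing: float
    level_index: int = 0

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("binary mask must be a 2-D raster")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        bad = np.setdiff1d(np.unique(self.data), [0, 1])
        if bad.size:
            raise ValueError(f"binary mask contains values other than 0/1: {bad}")

    @property
    def level(self) -> LevelRef:
        return LevelRef(self.level_index, self.spacing)


@dataclass
class SamplingMask:
    """Six-label raster steering training-patch selection.

    Labels: edge=1, artifacts=2, background=3, external_margin=4,
    internal_margin=5, tissue=6.  External/internal margins are the bands of
    background/tissue pixels within a fixed pixel radius (125 px by default)
    of the opposite class, measured at the mask's own level.
    """

    data: np.ndarray
    level: LevelRef
    margin_px: int = 125

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("sampling mask must be a 2-D raster")
        bad = np.setdiff1d(np.unique(self.data), list(LABEL_NAMES))
        if bad.size:
            raise ValueError(f"sampling mask contains unknown labels: {bad}")


@dataclass
class Annotation:
    """A labeled polygon in level-0 pixel coordinates.

    ``exterior`` is an (N, 2) array of (x, y) vertices (N >= 3); ``interiors``
    are optional hole rings (used for cleaned tissue regions whose annotated
    holes were kept).
    """

    exterior: np.ndarray
    label: str
    interiors: list = field(default_factory=list)

    def __post_init__(self):
        self.exterior = np.asarray(self.exterior, dtype=float)
        if self.exterior.ndim != 2 or self.exterior.shape[1] != 2:
            raise ValueError("exterior must be an (N, 2) vertex array")
        if len(self.exterior) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.label not in ANNOTATION_CLASSES:
            raise ValueError(
                f"unknown class {self.label!r}; expected one of {ANNOTATION_CLASSES}"
            )
        self.interiors = [np.asarray(r, dtype=float) for r in self.interiors]


@dataclass
class AnnotationSet:
    """All polygon annotations of one image."""

    annotations: list

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self):
        return len(self.annotations)

    def by_label(self, label: str) -> list:
        return [a for a in self.annotations if a.label == label]


def margin_physical_um(spacing_um: float, margin_px: int = 125) -> float:
    """Physical width in µm of a margin band of ``margin_px`` pixels."""
    return margin_px * spacing_um


def patch_field_of_view_um(spacing_um: float, patch_px: int = 128) -> float:
    """Physical field of view in µm of a square training patch."""
    return patch_px * spacing_um
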