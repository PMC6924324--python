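"""Reference-mask machinery: annotation cleanup, rasterization, margin
labels, binarization, and the shared post-processing.

The six-label sampling mask steers training-patch selection; for learning
and for evaluation it collapses to binary via: tissue = {tissue,
internal_margin}, non-tissue = {edge, artifacts, background,
external_margin}.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .core import (
    ARTIFACTS,
    BACKGROUND,
    EDGE,
    EXTERNAL_MARGIN,
    INTERNAL_MARGIN,
    TISSUE,
    TISSUE_LABELS,
    Annotation,
    AnnotationSet,
    BinaryMask,
    LevelRef,
    SamplingMask,
)

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity for foreground
_FOUR = ndimage.generate_binary_structure(2, 1)  # 4-connectivity for holes


def min_region_area_px(spacing_um: float, diameter_um: float = 250.0) -> float:
    """Pixel area below which a region's equivalent diameter is < ``diameter_um``.

    Equivalent diameter of a region of area A px^2 at spacing s µm/px is
    ``2 * sqrt(A / pi) * s``; it falls below d µm exactly when
    ``A < pi * (d / (2 s))^2``.
    """
    return math.pi * (diameter_um / (2.0 * spacing_um)) ** 2


# ---------------------------------------------------------------------------
# annotation cleanup (vector domain)

def _as_polygons(geom):
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    # GeometryCollection from degenerate buffers: keep polygonal parts
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


def clean_annotations(
    annotations: AnnotationSet,
    spacing_um: float,
    min_diameter_um: float = 250.0,
    merge_gap_um: float = 50.0,
) -> AnnotationSet:
    """Normalize tissue annotations the way the reference masks are defined.

    Tissue regions with equivalent diameter < ``min_diameter_um`` are
    removed, tissue areas separated by less than ``merge_gap_um`` are merged
    (morphological closing with a disc of radius ``merge_gap_um / 2``), and
    holes (annotated background inside tissue, or interior rings) with
    equivalent diameter < ``min_diameter_um`` are filled.  "Smaller than" is
    strict: a region of exactly ``min_diameter_um`` is retained.  Edge and
    inner-artifact annotations pass through unchanged; explicit background
    polygons are absorbed into interior rings of the cleaned tissue.

    Coordinates are level-0 pixels; ``spacing_um`` converts the physical
    thresholds into pixels.  The operation is idempotent.
    """
    if not spacing_um > 0:
        raise ValueError("spacing must be positive")
    tissue_polys = [
        Polygon(a.exterior, [r for r in a.interiors]) for a in annotations.by_label("tissue")
    ]
    if not tissue_polys:
        return AnnotationSet(
            [a for a in annotations if a.label in ("edge", "inner_artifact")]
        )
    geom = unary_union([p.buffer(0) for p in tissue_polys])
    holes = [Polygon(a.exterior) for a in annotations.by_label("background")]
    if holes:
        geom = geom.difference(unary_union([h.buffer(0) for h in holes]))

    min_area = min_region_area_px(spacing_um, min_diameter_um)
    parts = [p for p in _as_polygons(geom) if p.area >= min_area]

    r = merge_gap_um / 2.0 / spacing_um
    merged = unary_union(parts).buffer(r, quad_segs=32).buffer(-r, quad_segs=32)

    cleaned = []
    for poly in _as_polygons(merged):
        if poly.area < min_area:
            continue
        keep_rings = [
            np.asarray(ring.coords[:-1], dtype=float)
            for ring in poly.interiors
            if Polygon(ring).area >= min_area
        ]
        cleaned.append(
            Annotation(np.asarray(poly.exterior.coords[:-1], dtype=float), "tissue", keep_rings)
        )
    passthrough = [a for a in annotations if a.label in ("edge", "inner_artifact")]
    return AnnotationSet(cleaned + passthrough)


# ---------------------------------------------------------------------------
# rasterization (pixel-center, even-odd)

def polygon_mask(shape, rings, scale: float = 1.0) -> np.ndarray:
    """Rasterize polygon rings under the pixel-center even-odd rule.

    A pixel (x, y) is set iff its center (x + 0.5, y + 0.5) lies inside the
    polygon by even-odd crossing counting over *all* rings, so interior
    (hole) rings are excluded automatically.  ``scale`` divides the input
    coordinates (e.g. 2**level for a level-k raster of level-0 annotations).
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    segs = []
    for ring in rings:
        v = np.asarray(ring, dtype=float) / scale
        if len(v) < 3:
            continue
        nxt = np.roll(v, -1, axis=0)
        keep = v[:, 1] != nxt[:, 1]  # horizontal edges never cross a scanline
        segs.append(np.column_stack([v[keep], nxt[keep]]))
    if not segs:
        return out
    e = np.concatenate(segs)  # columns: x1 y1 x2 y2
    y_lo = max(0, int(math.floor(e[:, [1, 3]].min() - 0.5)))
    y_hi = min(h, int(math.ceil(e[:, [1, 3]].max())))
    x1, y1, x2, y2 = e.T
    for row in range(y_lo, y_hi):
        yc = row + 0.5
        m = ((y1 <= yc) & (yc < y2)) | ((y2 <= yc) & (yc < y1))
        if not m.any():
            continue
        xs = x1[m] + (yc - y1[m]) * (x2[m] - x1[m]) / (y2[m] - y1[m])
        xs.sort()
        for a, b in zip(xs[0::2], xs[1::2]):
            i0 = max(0, math.ceil(a - 0.5))
            i1 = min(w, math.ceil(b - 0.5))
            if i1 > i0:
                out[row, i0:i1] = True
    return out


#: paint order for rasterization; later entries overwrite earlier ones.
#: Explicit background polygons are painted last: they are annotated holes
#: in the tissue and must override it.
_PAINT_ORDER = (("edge", EDGE), ("inner_artifact", ARTIFACTS), ("tissue", TISSUE),
                ("background", BACKGROUND))


def rasterize(
    annotations: AnnotationSet,
    shape,
    level: LevelRef,
    scale: float = None,
) -> np.ndarray:
    """Convert polygon annotations to a four-label raster at ``level``.

    Every pixel receives exactly one of {tissue, background, edge,
    inner_artifact}; non-annotated pixels are background.  Annotations are in
    level-0 pixel coordinates and are divided by ``scale`` (default
    ``2**level_index``).  Polygons reaching outside the extent are clipped
    with a logged warning.
    """
    if scale is None:
        scale = 2.0**level.level_index
    raster = np.full(shape, BACKGROUND, dtype=np.uint8)
    h, w = shape
    for label, code in _PAINT_ORDER:
        for ann in annotations.by_label(label):
            ext = ann.exterior / scale
            if (ext[:, 0].min() < 0 or ext[:, 1].min() < 0
                    or ext[:, 0].max() > w or ext[:, 1].max() > h):
                log.warning("annotation extends outside the raster; clipping")
            m = polygon_mask(shape, [ann.exterior] + list(ann.interiors), scale)
            raster[m] = code
    return raster


def add_margins(raster: np.ndarray, level: LevelRef, margin_px: int = 125) -> SamplingMask:
    """Expand a four-label raster into the six-label sampling mask.

    Background pixels within ``margin_px`` (Euclidean, pixel centers, at the
    raster's own level) of any tissue pixel become external margin; tissue
    pixels within ``margin_px`` of any background pixel become internal
    margin.  Edge and artifact pixels keep their labels.
    """
    raster = np.asarray(raster)
    out = raster.copy()
    has_tissue = bool((raster == TISSUE).any())
    has_bg = bool((raster == BACKGROUND).any())
    if has_tissue and has_bg:
        d_to_tissue = ndimage.distance_transform_edt(raster != TISSUE)
        d_to_bg = ndimage.distance_transform_edt(raster != BACKGROUND)
        out[(raster == BACKGROUND) & (d_to_tissue <= margin_px)] = EXTERNAL_MARGIN
        out[(raster == TISSUE) & (d_to_bg <= margin_px)] = INTERNAL_MARGIN
    return SamplingMask(out, level, margin_px=margin_px)


def to_binary(mask: SamplingMask) -> BinaryMask:
    """Collapse the six labels to tissue (1) / non-tissue (0)."""
    data = mask.data
    bad = np.setdiff1d(np.unique(data), [EDGE, ARTIFACTS, BACKGROUND,
                                         EXTERNAL_MARGIN, INTERNAL_MARGIN, TISSUE])
    if bad.size:
        raise ValueError(f"unknown label values: {bad}")
    binary = np.isin(data, list(TISSUE_LABELS)).astype(np.uint8)
    return BinaryMask(binary, mask.level.spacing, mask.level.level_index)


def reference_mask(
    annotations: AnnotationSet, shape, level: LevelRef, spacing0_um: float = None
) -> BinaryMask:
    """Cleaned, rasterized, binarized reference tissue mask at ``level``."""
    spacing0 = spacing0_um if spacing0_um is not None else level.spacing / 2.0**level.level_index
    cleaned = clean_annotations(annotations, spacing0)
    raster = rasterize(cleaned, shape, level)
    return to_binary(add_margins(raster, level))


# ---------------------------------------------------------------------------
# shared post-processing

def postprocess(mask: BinaryMask, min_diameter_um: float = 250.0) -> BinaryMask:
    """Remove small regions, then fill small holes; applied to every method.

    Disjunctive foreground regions (8-connected) with equivalent diameter
    smaller than ``min_diameter_um`` are deleted; enclosed holes
    (4-connected background regions not touching the border) smaller than
    the same threshold are filled.  Idempotent.
    """
    data = mask.data.astype(bool)
    min_area = min_region_area_px(mask.spacing, min_diameter_um)

    lab, n = ndimage.label(data, structure=_EIGHT)
    if n:
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < min_area)
        small = small[small != 0]
        if small.size:
            data[np.isin(lab, small)] = False

    holes = ~data
    lab, n = ndimage.label(holes, structure=_FOUR)
    if n:
        border = np.unique(
            np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        )
        areas = np.bincount(lab.ravel())
        fill = np.flatnonzero(areas < min_area)
        fill = np.setdiff1d(fill, border)
        fill = fill[fill != 0]
        if fill.size:
            data[np.isin(lab, fill)] = True

    return BinaryMask(data.astype(np.uint8), mask.spacing, mask.level_index)
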