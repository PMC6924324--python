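"""Multiresolution (pyramidal) TIFF image handling.

A whole-slide image is stored as a pyramid of RGB rasters in which each
consecutive level halves the pixel count per axis and doubles the pixel
spacing.  This module reads and writes such pyramids with :mod:`tifffile`,
exposes per-level pixel spacing, selects levels by target spacing, and reads
(white-padded) regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .core import BinaryMask, LevelRef

_UM_PER_CM = 10_000.0
_SPACING_RATIO_RANGE = (1.9, 2.1)


class PyramidError(ValueError):
    """Raised for unusable pyramid inputs."""


@dataclass
class ImagePyramid:
    """An in-memory multiresolution RGB image.

    ``levels[k]`` is an (H, W, 3) uint8 raster, ``spacings[k]`` its isotropic
    pixel size in µm.  Consecutive levels halve the pixel counts (up to one
    pixel of rounding slack, to accommodate TIFF dialect variance) and double
    the spacing (ratio within [1.9, 2.1]).
    """

    levels: list
    spacings: list
    validate: bool = True

    def __post_init__(self):
        self.levels = [np.ascontiguousarray(lv) for lv in self.levels]
        self.spacings = [float(s) for s in self.spacings]
        if self.validate:
            self.check()

    def check(self):
        if not self.levels:
            raise PyramidError("pyramid has no levels")
        if len(self.levels) != len(self.spacings):
            raise PyramidError("one spacing per level is required")
        for k, lv in enumerate(self.levels):
            if lv.ndim != 3 or lv.shape[2] != 3 or lv.dtype != np.uint8:
                raise PyramidError(f"level {k} is not an 8-bit RGB raster")
        for k in range(len(self.levels) - 1):
            ratio = self.spacings[k + 1] / self.spacings[k]
            if not _SPACING_RATIO_RANGE[0] <= ratio <= _SPACING_RATIO_RANGE[1]:
                raise PyramidError(
                    f"spacing ratio {ratio:.3f} between levels {k} and {k + 1} "
                    f"outside {_SPACING_RATIO_RANGE}"
                )
            for axis in (0, 1):
                expect = math.ceil(self.levels[k].shape[axis] / 2)
                got = self.levels[k + 1].shape[axis]
                if abs(got - expect) > 1:
                    raise PyramidError(
                        f"level {k + 1} axis {axis} has {got} pixels, "
                        f"expected ~{expect}"
                    )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def dimensions(self) -> list:
        """Per-level (width, height) in pixels."""
        return [(lv.shape[1], lv.shape[0]) for lv in self.levels]

    def level_ref(self, index: int) -> LevelRef:
        return LevelRef(index, self.spacings[index])


def closest_level(pyramid: ImagePyramid, target_spacing: float) -> LevelRef:
    """Select the pyramid level whose pixel spacing is closest to the target.

    Ties (a target exactly between two level spacings) resolve to the lower,
    i.e. finer, level index.
    """
    if pyramid.n_levels == 0:
        raise PyramidError("cannot select a level from an empty pyramid")
    if not target_spacing > 0:
        raise ValueError("target_spacing must be positive")
    best = min(
        range(pyramid.n_levels),
        key=lambda k: (abs(pyramid.spacings[k] - target_spacing), k),
    )
    return pyramid.level_ref(best)


def read_region(pyramid, level, origin, size, fill=255) -> np.ndarray:
    """Read a (possibly padded) tile from one level.

    ``origin=(x, y)`` and ``size=(w, h)`` are in pixels of that level; the
    region is half-open.  Pixels outside the level extent are filled with
    white (255, 255, 255) so that out-of-slide area looks like background.
    A region with no overlap with the level raises :class:`PyramidError`.
    """
    idx = level.level_index if isinstance(level, LevelRef) else int(level)
    raster = pyramid.levels[idx]
    x, y = int(origin[0]), int(origin[1])
    w, h = int(size[0]), int(size[1])
    if w <= 0 or h <= 0:
        raise ValueError("size must be positive")
    H, W = raster.shape[:2]
    if x + w <= 0 or y + h <= 0 or x >= W or y >= H:
        raise PyramidError("requested region lies fully outside the level extent")
    out = np.full((h, w) + raster.shape[2:], fill, dtype=raster.dtype)
    sx0, sy0 = max(x, 0), max(y, 0)
    sx1, sy1 = min(x + w, W), min(y + h, H)
    out[sy0 - y : sy1 - y, sx0 - x : sx1 - x] = raster[sy0:sy1, sx0:sx1]
    return out


def _resolution_tag(spacing_um: float):
    ppcm = _UM_PER_CM / spacing_um
    return (ppcm, ppcm)


def write_pyramid(pyramid: ImagePyramid, path, compression="zlib"):
    """Write an RGB pyramid as a tiled multi-page TIFF with resolution tags."""
    with tifffile.TiffWriter(path) as tif:
        for k, lv in enumerate(pyramid.levels):
            tif.write(
                lv,
                photometric="rgb",
                compression=compression,
                tile=(256, 256),
                resolution=_resolution_tag(pyramid.spacings[k]),
                resolutionunit="CENTIMETER",
                subfiletype=0 if k == 0 else 1,
            )


def _spacing_from_page(page):
    try:
        num, den = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    if den == 0 or num == 0:
        return None
    ppu = num / den
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimeter
        return _UM_PER_CM / ppu
    if unit == 2:  # inch
        return 25_400.0 / ppu
    return None


def read_pyramid(path, pixel_spacing_um=None) -> ImagePyramid:
    """Read a multiresolution TIFF into memory.

    Pixel spacing is taken from the TIFF resolution tags; when the file
    carries none, ``pixel_spacing_um`` (the level-0 spacing; config key
    ``pixel_spacing_um``) must be supplied and coarser levels are assigned
    doubled spacings.
    """
    with tifffile.TiffFile(path) as tif:
        pages = list(tif.pages)
        levels, spacings = [], []
        for k, page in enumerate(pages):
            arr = page.asarray()
            if arr.ndim == 2:
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            levels.append(np.ascontiguousarray(arr, dtype=np.uint8))
            spacings.append(_spacing_from_page(page))
    if any(s is None for s in spacings):
        if pixel_spacing_um is None:
            raise PyramidError(
                f"{path}: no resolution metadata; supply pixel_spacing_um"
            )
        spacings = [pixel_spacing_um * 2.0**k for k in range(len(levels))]
    return ImagePyramid(levels, spacings)


def majority_downsample(mask: np.ndarray) -> np.ndarray:
    """Downsample a binary raster by 2x2 majority vote (ties become 1).

    Odd-sized axes are padded with background (0) so the output has
    ``ceil(n / 2)`` pixels per axis, matching pyramid dimension rules.
    """
    m = np.asarray(mask, dtype=np.uint8)
    h, w = m.shape
    ph, pw = -h % 2, -w % 2
    cnt = np.ones_like(m)
    if ph or pw:
        m = np.pad(m, ((0, ph), (0, pw)))
        cnt = np.pad(cnt, ((0, ph), (0, pw)))

    def block_sum(a):
        return (a[0::2, 0::2].astype(np.int16) + a[0::2, 1::2]
                + a[1::2, 0::2] + a[1::2, 1::2])

    ones = block_sum(m)
    total = block_sum(cnt)  # partial edge blocks vote over real pixels only
    return (2 * ones >= total).astype(np.uint8)


def write_mask_pyramid(mask: BinaryMask, path, n_levels=None, compression="zlib"):
    """Write a binary mask as a tiled multiresolution TIFF.

    Level 0 equals the mask bit-exactly; coarser levels are produced by 2x2
    majority vote (ties counted as tissue, which preserves thin strands).
    By default levels are added until the smaller axis drops below 256 px.
    """
    levels = [np.ascontiguousarray(mask.data, dtype=np.uint8)]
    spacings = [mask.spacing]
    while True:
        if n_levels is not None:
            if len(levels) >= n_levels:
                break
        elif min(levels[-1].shape) < 256:
            break
        levels.append(majority_downsample(levels[-1]))
        spacings.append(spacings[-1] * 2.0)
        if levels[-1].size <= 1:
            break
    with tifffile.TiffWriter(path) as tif:
        for k, lv in enumerate(levels):
            tile = (256, 256) if min(lv.shape) >= 16 else None
            tif.write(
                lv,
                photometric="minisblack",
                compression=compression,
                tile=tile,
                resolution=_resolution_tag(spacings[k]),
                resolutionunit="CENTIMETER",
                subfiletype=0 if k == 0 else 1,
            )


def read_mask_pyramid(path, pixel_spacing_um=None):
    """Read a mask pyramid back as a list of (raster, spacing) pairs."""
    with tifffile.TiffFile(path) as tif:
        out = []
        for k, page in enumerate(tif.pages):
            spacing = _spacing_from_page(page)
            if spacing is None:
                if pixel_spacing_um is None:
                    raise PyramidError(f"{path}: no resolution metadata")
                spacing = pixel_spacing_um * 2.0**k
            out.append((np.ascontiguousarray(page.asarray()), spacing))
    return out
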