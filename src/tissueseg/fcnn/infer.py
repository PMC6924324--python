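"""Whole-image fully convolutional inference.

The trained classifier slides over an entire pyramid level in overlapping
tiles.  Each tile carries a halo of real context at least as wide as half
the receptive field, and the polluted border of its output map is cropped,
so the stitched probability map is identical to a single whole-image pass
(tile seams are invisible).  The map lives on a grid 8x coarser than the
level; it is upsampled back to level resolution and thresholded at t = 0.8
(inclusive: p >= t is tissue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ..core import BinaryMask, LevelRef
from ..pyramid import ImagePyramid, closest_level

#: probability threshold tuned on the development validation split
DEFAULT_THRESHOLD = 0.8


@dataclass
class ProbabilityMap:
    """Tissue probabilities on the network's output grid.

    ``factor`` is the grid pitch in level pixels: 8 for a plain pass,
    ``8 / refine`` after shift-and-stitch refinement.
    """

    probs: np.ndarray
    level: LevelRef
    factor: int = 8

    def __post_init__(self):
        if self.probs.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if self.probs.min() < 0.0 or self.probs.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")

    def upsample(self, shape, mode: str = "nearest") -> np.ndarray:
        """Back to level resolution; nearest is the seam-safe default."""
        f = self.factor
        if mode == "nearest":
            up = np.repeat(np.repeat(self.probs, f, axis=0), f, axis=1)
        elif mode == "bilinear":
            up = resize(self.probs, (self.probs.shape[0] * f,
                                     self.probs.shape[1] * f),
                        order=1, mode="edge", anti_aliasing=False,
                        preserve_range=True)
        else:
            raise ValueError(f"unknown upsampling mode {mode!r}")
        return up[: shape[0], : shape[1]]


def _pad_to_multiple(img: np.ndarray, factor: int, fill=255) -> np.ndarray:
    h, w = img.shape[:2]
    ph, pw = -h % factor, -w % factor
    if not (ph or pw):
        return img
    return np.pad(img, ((0, ph), (0, pw), (0, 0)), constant_values=fill)


def _prob_grid(model, img_u8: np.ndarray, tile, halo) -> np.ndarray:
    """Probability grid (pitch = downsampling factor) over one raster."""
    factor = model.spec.downsample_factor
    rf = model.spec.receptive_field
    padded = _pad_to_multiple(img_u8, factor)
    hp, wp = padded.shape[:2]
    x = padded.astype(np.float32) / 255.0

    if tile is None:
        return model.forward(x[None])[0, :, :, 1]

    if tile % factor or halo % factor:
        raise ValueError(f"tile and halo must be multiples of {factor}")
    if tile + 2 * halo < rf:
        raise ValueError(f"tile too small for the {rf} px receptive field")
    if 2 * halo < rf - 1:
        raise ValueError(
            f"halo {halo} px does not cover half the {rf} px receptive field"
        )
    out = np.empty((hp // factor, wp // factor), dtype=np.float32)
    for oy in range(0, hp, tile):
        for ox in range(0, wp, tile):
            y0, x0 = max(0, oy - halo), max(0, ox - halo)
            y1 = min(hp, oy + tile + halo)
            x1 = min(wp, ox + tile + halo)
            p = model.forward(x[None, y0:y1, x0:x1])[0, :, :, 1]
            cy0 = (oy - y0) // factor
            cx0 = (ox - x0) // factor
            ny = (min(oy + tile, hp) - oy) // factor
            nx = (min(ox + tile, wp) - ox) // factor
            out[oy // factor : oy // factor + ny,
                ox // factor : ox // factor + nx] = p[cy0 : cy0 + ny,
                                                      cx0 : cx0 + nx]
    return out


def infer_probabilities(model, pyramid: ImagePyramid, spacing: float,
                        tile: int = 256, halo: int = 32,
                        refine: int = 1) -> ProbabilityMap:
    """Dense tissue probabilities for the level closest to ``spacing``.

    ``tile=None`` runs a single whole-image pass (memory permitting);
    otherwise the level is processed in ``tile``-pixel steps with ``halo``
    pixels of context on every interior side.  Both must be multiples of
    the downsampling factor, and the halo must cover half the receptive
    field so tiling is exact.

    ``refine`` is the shift-and-stitch factor: the network is applied to
    ``refine**2`` diagonally shifted copies of the level and the outputs
    interleaved, reducing the map pitch from 8 px to ``8 / refine`` px at
    ``refine**2`` times the cost.  Useful when regions are only tens of
    pixels wide at the evaluated level.
    """
    level = closest_level(pyramid, spacing)
    img = pyramid.levels[level.level_index]
    factor = model.spec.downsample_factor
    if refine < 1 or factor % refine:
        raise ValueError(f"refine must divide the {factor} px output pitch")
    if refine == 1:
        return ProbabilityMap(_prob_grid(model, img, tile, halo), level, factor)

    step = factor // refine
    base = _prob_grid(model, img, tile, halo)
    fine = np.empty((base.shape[0] * refine, base.shape[1] * refine),
                    dtype=np.float32)
    for oi in range(refine):
        for oj in range(refine):
            if oi == 0 and oj == 0:
                grid = base
            else:
                # dropping o pixels at the top/left samples positions 8k + o
                shifted = img[oi * step :, oj * step :]
                grid = _prob_grid(model, shifted, tile, halo)
                pad = (base.shape[0] - grid.shape[0],
                       base.shape[1] - grid.shape[1])
                if pad[0] > 0 or pad[1] > 0:  # shift crossed a pitch boundary
                    grid = np.pad(grid, ((0, max(pad[0], 0)),
                                         (0, max(pad[1], 0))), mode="edge")
            fine[oi::refine, oj::refine] = grid[: base.shape[0], : base.shape[1]]
    return ProbabilityMap(fine, level, step)


def infer(model, pyramid: ImagePyramid, spacing: float,
          threshold: float = DEFAULT_THRESHOLD, tile: int = 256,
          halo: int = 32, upsample: str = "nearest",
          refine: int = 1) -> BinaryMask:
    """Binary tissue mask at the level closest to ``spacing``.

    The caller applies the shared post-processing afterwards, exactly as
    for the classical methods.
    """
    pmap = infer_probabilities(model, pyramid, spacing, tile=tile, halo=halo,
                               refine=refine)
    level = pmap.level
    shape = pyramid.levels[level.level_index].shape[:2]
    up = pmap.upsample(shape, mode=upsample)
    return BinaryMask((up >= threshold).astype(np.uint8), level.spacing,
                      level.level_index)
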