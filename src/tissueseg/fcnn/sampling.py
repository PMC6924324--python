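"""Class-weighted patch sampling from six-label sampling masks.

A class is drawn with probability proportional to its weight among the
classes actually present in the mask; a pixel of that class is then drawn
uniformly and becomes the patch center.  The label patch delivered with the
image patch is the binary (tissue / non-tissue) view of the same window.
"""

from __future__ import annotations

import logging

import numpy as np

from ..core import LABEL_NAMES, SamplingMask
from ..masks import to_binary
from ..pyramid import ImagePyramid, read_region

log = logging.getLogger(__name__)

#: sampling weights in label-code order (edge, artifacts, background,
#: external_margin, internal_margin, tissue); the internal margin is
#: oversampled 5x because the tissue boundary is where segmenters disagree
DEFAULT_CLASS_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 5.0, 1.0)


def draw_class(present, weights, rng: np.random.Generator) -> int:
    """Draw one label code from ``present`` with the given per-class weights.

    ``weights`` is indexed by label code - 1 (six entries).  Classes absent
    from ``present`` are excluded and the remaining weights renormalized.
    """
    present = sorted(present)
    if not present:
        raise ValueError("no classes present to sample from")
    w = np.array([weights[c - 1] for c in present], dtype=float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    return int(rng.choice(present, p=w / w.sum()))


class PatchSampler:
    """Draws training patches from one or more (pyramid, masks) pairs.

    ``items`` is a list of ``(ImagePyramid, {spacing: SamplingMask})``; the
    mask spacing keys must correspond to pyramid levels.  For each draw the
    source image is chosen uniformly, then the class, then the center pixel.
    """

    def __init__(self, items, patch_px: int = 128,
                 weights=DEFAULT_CLASS_WEIGHTS):
        self.items = items
        self.patch_px = patch_px
        self.weights = tuple(weights)
        self._index = {}  # (item, spacing) -> {label: flat pixel indices}
        self._binary = {}  # (item, spacing) -> uint8 tissue raster
        for i, (_, masks) in enumerate(items):
            for spacing, mask in masks.items():
                labels = {}
                data = mask.data
                for code in LABEL_NAMES:
                    idx = np.flatnonzero(data == code)
                    if idx.size:
                        labels[code] = idx
                if not labels:
                    raise ValueError("sampling mask has no labeled pixels")
                self._index[(i, spacing)] = labels
                self._binary[(i, spacing)] = to_binary(mask).data

    def spacings(self, item: int = 0):
        return sorted(s for (i, s) in self._index if i == item)

    def sample(self, spacing: float, rng: np.random.Generator,
               patch_px: int = None):
        """Return ``(rgb_patch, label_patch, meta)`` for one draw.

        The RGB patch is uint8 (patch_px, patch_px, 3), white-padded when the
        window leaves the slide; the label patch is the binary tissue mask of
        the same window, zero-padded (outside the slide is non-tissue).
        """
        patch_px = patch_px or self.patch_px
        i = int(rng.integers(len(self.items)))
        pyramid, masks = self.items[i]
        mask = masks[spacing]
        labels = self._index[(i, spacing)]
        cls = draw_class(labels.keys(), self.weights, rng)
        flat = labels[cls]
        center = int(flat[rng.integers(flat.size)])
        h, w = mask.data.shape
        cy, cx = divmod(center, w)
        x0 = cx - patch_px // 2
        y0 = cy - patch_px // 2
        rgb = read_region(pyramid, mask.level, (x0, y0), (patch_px, patch_px))
        binary = self._binary[(i, spacing)]
        lab = np.zeros((patch_px, patch_px), dtype=np.uint8)
        sy0, sx0 = max(y0, 0), max(x0, 0)
        sy1 = min(y0 + patch_px, h)
        sx1 = min(x0 + patch_px, w)
        lab[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = binary[sy0:sy1, sx0:sx1]
        return rgb, lab, {"item": i, "class": cls, "center": (cx, cy)}


def pool_labels(label_patch: np.ndarray, factor: int = 8,
                rule: str = "any") -> np.ndarray:
    """Downsample a binary label patch to the output grid.

    ``rule="any"``: a coarse cell is tissue if any of its pixels is tissue
    (sensitivity-first, but dilates the boundary by up to ``factor - 1`` px,
    which costs real Dice when regions are only tens of pixels wide).
    ``rule="majority"``: tissue iff at least half the cell is tissue
    (unbiased boundary placement).
    ``rule="fraction"``: the float tissue fraction of the cell — a soft
    target; a network trained on it predicts per-cell tissue coverage, so
    interpolating its probability map recovers the boundary with sub-cell
    precision.
    """
    h, w = label_patch.shape
    h2, w2 = h // factor, w // factor
    r = label_patch[: h2 * factor, : w2 * factor]
    blocks = r.reshape(h2, factor, w2, factor)
    if rule == "any":
        return blocks.max(axis=(1, 3))
    if rule == "majority":
        s = blocks.astype(np.int32).sum(axis=(1, 3))
        return (2 * s >= factor * factor).astype(label_patch.dtype)
    if rule == "fraction":
        return blocks.astype(np.float32).mean(axis=(1, 3))
    raise ValueError(f"unknown pooling rule {rule!r}")
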