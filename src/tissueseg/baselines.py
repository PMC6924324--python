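"""Classical tissue segmenters: fixed threshold, Otsu, and FESI.

All three operate on a single pyramid level and return a raw binary mask;
the shared :func:`tissueseg.masks.postprocess` is applied by the caller so
that every method is evaluated under identical post-processing.

Tissue is the *dark* class for both thresholding methods: histology
background is near-white, so a pixel is tissue iff its grayscale value is
strictly below the threshold (pixels equal to the threshold are background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import BinaryMask, LevelRef

#: fixed grayscale threshold tuned on the development validation split
DEFAULT_FIXED_THRESHOLD = 217.0


def grayscale(rgb: np.ndarray) -> np.ndarray:
    """Unweighted mean of the R, G and B channels, as float64."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return rgb.astype(np.float64).mean(axis=2)


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask)


def _closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing that does not erode the image border.

    The raster is padded by the disc radius before dilation/erosion, so
    tissue touching the border is preserved (scipy's zero boundary would
    shave it off).
    """
    structure = disk(radius)
    padded = np.pad(mask, radius)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure), structure, border_value=1
    )
    return closed[radius:-radius, radius:-radius]


def fixed_threshold_segment(
    rgb: np.ndarray,
    level: LevelRef,
    threshold: float = DEFAULT_FIXED_THRESHOLD,
    closing_radius: int = 2,
) -> BinaryMask:
    """Threshold the grayscale image at a fixed value.

    Tissue iff gray < threshold, then hole filling and morphological closing
    (disc of ``closing_radius`` px) refine the raw mask.
    """
    tissue = grayscale(rgb) < threshold
    tissue = _fill_holes(tissue)
    if closing_radius > 0:
        tissue = _closing(tissue, closing_radius)
    return BinaryMask(tissue.astype(np.uint8), level.spacing, level.level_index)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's optimal split of a 256-bin grayscale histogram.

    Returns the threshold level ``t`` (1..255) for which splitting pixels
    into ``value < t`` versus ``value >= t`` minimizes the combined
    intra-class variance (equivalently maximizes the between-class
    variance).  Ties resolve to the lowest level.  A histogram with fewer
    than two non-empty bins has no two classes to separate and raises
    ``ValueError``.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or len(hist) != 256:
        raise ValueError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than two non-empty bins")
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels with value <= k
    m0 = np.cumsum(hist * bins)
    total, total_m = w0[-1], m0[-1]
    # candidate thresholds t = k + 1 split into [0..k] and [k+1..255]
    w0, m0 = w0[:-1], m0[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, m0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (total_m - m0) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(between)) + 1


def otsu_segment(rgb: np.ndarray, level: LevelRef) -> BinaryMask:
    """Adaptive thresholding: Otsu's split of the grayscale histogram."""
    gray = grayscale(rgb)
    quantized = np.clip(gray, 0, 255).astype(np.uint8)
    hist = np.bincount(quantized.ravel(), minlength=256)
    t = otsu_threshold(hist)
    tissue = quantized < t
    return BinaryMask(tissue.astype(np.uint8), level.spacing, level.level_index)


@dataclass
class FesiParams:
    """Tuning constants for FESI (foreground extraction from structure
    information).

    The 100/100 seed rule comes from the original method: a
    distance-transform maximum is accepted as a tissue seed if its value
    exceeds ``seed_accept_distance_value`` px or lies within
    ``seed_proximity`` px of a previously accepted seed.  Kernel sizes are
    implementation choices exposed for tuning.
    """

    seed_accept_distance_value: float = 100.0
    seed_proximity: float = 100.0
    gaussian_sigma: float = 2.0
    median_size: int = 5
    opening_radius: int = 2

    def __post_init__(self):
        for name in ("seed_accept_distance_value", "seed_proximity",
                     "gaussian_sigma", "median_size", "opening_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


_EIGHT = np.ones((3, 3), dtype=bool)


def fesi_segment(rgb: np.ndarray, level: LevelRef, params: FesiParams = None) -> BinaryMask:
    """Edge-based tissue extraction with flood-filled background.

    Pipeline: grayscale -> |Laplacian| -> Gaussian blur -> global threshold
    at the image mean -> median blur -> morphological opening -> flood fill
    of the background starting from the point furthest from any tissue
    (which fills holes inside tissue) -> iterative acceptance of
    distance-transform maxima under the 100/100 seed rule, dropping the
    regions of rejected seeds.
    """
    if params is None:
        params = FesiParams()
    gray = grayscale(rgb)
    lap = np.abs(ndimage.laplace(gray))
    blurred = ndimage.gaussian_filter(lap, sigma=params.gaussian_sigma)
    fg = blurred > blurred.mean()
    if not fg.any() or fg.all():
        empty = np.zeros(gray.shape, dtype=np.uint8) if not fg.any() else fg.astype(np.uint8)
        return BinaryMask(empty, level.spacing, level.level_index)
    fg = ndimage.median_filter(fg.astype(np.uint8), size=params.median_size).astype(bool)
    fg = ndimage.binary_opening(fg, structure=disk(params.opening_radius), border_value=0)
    if not fg.any():
        return BinaryMask(fg.astype(np.uint8), level.spacing, level.level_index)

    # flood fill the background from the point with maximal distance to any
    # tissue pixel; unreached non-foreground areas are holes -> tissue
    d_to_fg = ndimage.distance_transform_edt(~fg)
    seed = np.unravel_index(np.argmax(d_to_fg), d_to_fg.shape)
    bg_labels, _ = ndimage.label(~fg, structure=_EIGHT)
    background = bg_labels == bg_labels[seed]
    tissue = ~background

    tissue = _seed_filter(tissue, params)
    return BinaryMask(tissue.astype(np.uint8), level.spacing, level.level_index)


def _seed_filter(tissue: np.ndarray, params: FesiParams) -> np.ndarray:
    """Drop small tissue regions via the distance-maximum seed rule.

    Local maxima of the tissue distance transform are visited in decreasing
    order.  A maximum becomes an accepted seed when its distance value
    exceeds the acceptance threshold or it lies within the proximity radius
    of a previously accepted seed; its 8-connected region is then marked as
    tissue.  Regions none of whose maxima are accepted are removed.
    """
    dist = ndimage.distance_transform_edt(tissue)
    labels, n = ndimage.label(tissue, structure=_EIGHT)
    if n == 0:
        return tissue
    is_max = tissue & (dist >= ndimage.maximum_filter(dist, size=3))
    ys, xs = np.nonzero(is_max)
    values = dist[ys, xs]
    order = np.argsort(-values, kind="stable")
    ys, xs, values = ys[order], xs[order], values[order]

    accepted = np.zeros(n + 1, dtype=bool)
    seeds = np.empty((len(ys), 2), dtype=float)
    n_seeds = 0
    for y, x, value in zip(ys, xs, values):
        near = (
            n_seeds > 0
            and (((seeds[:n_seeds] - (y, x)) ** 2).sum(axis=1).min()
                 <= params.seed_proximity**2)
        )
        if value > params.seed_accept_distance_value or near:
            accepted[labels[y, x]] = True
            seeds[n_seeds] = (y, x)
            n_seeds += 1
    return accepted[labels]


def segment(method: str, rgb: np.ndarray, level: LevelRef, **kwargs) -> BinaryMask:
    """Dispatch to a classical segmenter by name (fixed | otsu | fesi)."""
    if method == "fixed":
        return fixed_threshold_segment(rgb, level, **kwargs)
    if method == "otsu":
        return otsu_segment(rgb, level, **kwargs)
    if method == "fesi":
        return fesi_segment(rgb, level, **kwargs)
    raise ValueError(f"unknown method {method!r}")
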