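"""Synthetic pyramidal histology fixtures with ground-truth annotations.

The generator emulates the difficulty axes of scanned slides: near-white
background, stained tissue blobs with nucleus-like dark dots on a textured
cytoplasm, sparse "fatty" tissue rendered as thin colored membranes around
near-white lobules (the classic failure mode of grayscale thresholding),
out-of-focus regions, and slide artifacts (air bubbles, coverslip edge, pen
markings, stain residue).  Every image comes with polygon ground truth in
level-0 pixel coordinates, so all other modules are testable without any
real whole-slide image.

It does *not* attempt photorealism: no scanner noise model, no stain
deconvolution physics, no tissue morphology beyond blob outlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.color import hsv2rgb

from .core import Annotation, AnnotationSet
from .masks import polygon_mask
from .pyramid import ImagePyramid


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic slide.

    Geometry is chosen so the default image is stable under annotation
    cleanup: blob diameters are far above 250 µm and pairwise gaps far above
    50 µm at the default 0.5 µm level-0 spacing.
    """

    canvas: int = 2048              # square level-0 side, px
    spacing: float = 0.5            # level-0 pixel spacing, µm
    n_levels: int = 5               # 0.5 .. 8.0 µm
    n_blobs: int = 2
    blob_diameter_px: tuple = (560, 800)
    fatty_fraction: float = 0.0     # fraction of blobs rendered fatty
    stain_hue_deg: float = 300.0    # H&E-like purple-pink
    stain_saturation: float = 0.45
    air_bubble: bool = False
    coverslip_edge: bool = False
    pen_mark: bool = False
    stain_residue: bool = False
    blur_fraction: float = 0.0      # area fraction rendered out of focus
    background_gray: float = 245.0
    background_sd: float = 2.0
    flat_tissue_gray: float = None  # render blobs flat at this gray (pure fixture)
    include_hole: bool = False      # punch a background-annotated hole in blob 0
    seed: int = 0

    def __post_init__(self):
        for name in ("fatty_fraction", "blur_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


class CanvasTooSmall(ValueError):
    pass


def _blob_polygon(rng, center, radius, n_vertices=64):
    """Smooth star-shaped polygon: r(θ) = R (1 + Σ a_k cos kθ + φ_k)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, 1.0)
    for k in range(2, 7):
        r += rng.uniform(-0.04, 0.04) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r *= radius
    x = center[0] + r * np.cos(theta)
    y = center[1] + r * np.sin(theta)
    return np.column_stack([x, y])


def _circle_polygon(center, radius, n_vertices=48):
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def _place_blobs(rng, spec):
    """Rejection-sample non-overlapping blob centers with > 100 px gaps.

    The whole layout is re-drawn when one blob cannot be placed, so an
    unlucky central first blob does not doom the sample.
    """
    margin = 16
    lo, hi = spec.blob_diameter_px
    if 1.2 * hi + 2 * margin >= spec.canvas:
        raise CanvasTooSmall(
            f"blob diameter {hi} px does not fit a {spec.canvas} px canvas"
        )
    for _restart in range(60):
        placed = []  # (center, radius)
        for _ in range(spec.n_blobs):
            radius = rng.uniform(lo, hi) / 2.0
            ok = False
            for _attempt in range(120):
                c = rng.uniform(1.2 * radius + margin,
                                spec.canvas - 1.2 * radius - margin, size=2)
                # 1.25 x radius bounds the star-shape wobble; keep >50 µm gaps
                if all(
                    np.hypot(*(c - pc)) > 1.25 * (radius + pr) + 110
                    for pc, pr in placed
                ):
                    ok = True
                    break
            if not ok:
                break
            placed.append((c, radius))
        if len(placed) == spec.n_blobs:
            return placed
    raise CanvasTooSmall(
        f"cannot place {spec.n_blobs} blobs of diameter "
        f"{spec.blob_diameter_px} on a {spec.canvas} px canvas"
    )


def _stain_hsv(spec, value):
    h = (spec.stain_hue_deg % 360.0) / 360.0
    return h, spec.stain_saturation, value


def _render_tissue(rng, img, blob_mask, spec, fatty):
    """Paint one blob in place; img is float RGB in [0, 1]."""
    ys, xs = np.nonzero(blob_mask)
    if spec.flat_tissue_gray is not None:
        img[ys, xs] = spec.flat_tissue_gray / 255.0
        return
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = blob_mask[y0:y1, x0:x1]
    h, w = sub.shape
    if fatty:
        # Voronoi membranes: thin stained walls around near-white lobules
        n_centers = max(8, int(sub.sum() / 1600))
        centers = rng.uniform(0, [h, w], size=(n_centers, 2))
        pts = np.column_stack(np.nonzero(sub))
        d, _ = cKDTree(centers).query(pts, k=2)
        membrane = (d[:, 1] - d[:, 0]) < 5.0
        hue, sat, _ = _stain_hsv(spec, 0.0)
        hsv = np.zeros((len(pts), 3))
        hsv[:, 0] = hue
        # lobule interiors: nearly white, faintly tinted
        hsv[:, 1] = np.where(membrane, sat, 0.02)
        hsv[:, 2] = np.where(membrane, 0.55, 0.965)
        img[pts[:, 0] + y0, pts[:, 1] + x0] = hsv2rgb(hsv[None])[0]
    else:
        value = np.full((h, w), 0.72)
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 5.0)
        noise /= max(np.abs(noise).max(), 1e-9)
        value += 0.07 * noise
        sat = np.full((h, w), spec.stain_saturation)
        # nucleus-like dark dots
        n_dots = max(12, int(sub.sum() / 900))
        cy = rng.integers(0, h, n_dots)
        cx = rng.integers(0, w, n_dots)
        rr = rng.uniform(1.5, 3.5, n_dots)
        for yy, xx, r in zip(cy, cx, rr):
            ys_ = slice(max(0, int(yy - r - 1)), min(h, int(yy + r + 2)))
            xs_ = slice(max(0, int(xx - r - 1)), min(w, int(xx + r + 2)))
            gy, gx = np.mgrid[ys_, xs_]
            dot = (gy - yy) ** 2 + (gx - xx) ** 2 <= r**2
            value[ys_, xs_][dot] = 0.30
            sat[ys_, xs_][dot] = min(1.0, spec.stain_saturation + 0.25)
        hue = np.full((h, w), (spec.stain_hue_deg % 360.0) / 360.0)
        rgb = hsv2rgb(np.dstack([hue, sat, np.clip(value, 0.0, 1.0)]))
        img[y0:y1, x0:x1][sub] = rgb[sub]


def _mean_downsample_rgb(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    if h % 2 or w % 2:
        img = np.pad(img, ((0, h % 2), (0, w % 2), (0, 0)), mode="edge")
        h, w = img.shape[:2]
    out = img.reshape(h // 2, 2, w // 2, 2, 3).astype(np.float32).mean(axis=(1, 3))
    return np.rint(out).astype(np.uint8)


def generate(spec: SyntheticSpec):
    """Render one synthetic slide.

    Returns ``(ImagePyramid, AnnotationSet)``; deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas
    annotations = []

    # background: near-white with mild sensor-like noise
    gray = rng.normal(spec.background_gray, spec.background_sd, size=(n, n))
    img = np.clip(gray, 225, 255)[:, :, None].repeat(3, axis=2) / 255.0
    img[:, :, 2] *= 0.998  # faint warm cast

    blobs = _place_blobs(rng, spec)
    n_fatty = int(round(spec.fatty_fraction * len(blobs)))
    fatty_flags = [i < n_fatty for i in range(len(blobs))]
    rng.shuffle(fatty_flags)

    hole_ann = None
    for i, (center, radius) in enumerate(blobs):
        poly = _blob_polygon(rng, center, radius)
        rings = [poly]
        if spec.include_hole and i == 0:
            hole_r = max(0.28 * radius, 1.15 * (125.0 / spec.spacing))
            hole = _circle_polygon(center, hole_r)
            rings.append(hole)
            hole_ann = Annotation(hole, "background")
        mask = polygon_mask((n, n), rings)
        _render_tissue(rng, img, mask, spec, fatty_flags[i])
        annotations.append(Annotation(poly, "tissue"))
    if hole_ann is not None:
        annotations.append(hole_ann)

    # artifacts -------------------------------------------------------------
    if spec.coverslip_edge:
        x = rng.integers(6, 18)
        wdt = rng.integers(5, 9)
        rect = np.array([(x, 0), (x + wdt, 0), (x + wdt, n), (x, n)], dtype=float)
        m = polygon_mask((n, n), [rect])
        img[m] = rng.uniform(0.35, 0.5)
        annotations.append(Annotation(rect, "edge"))
    if spec.air_bubble:
        c = rng.uniform(0.15 * n, 0.85 * n, size=2)
        r = rng.uniform(0.04 * n, 0.08 * n)
        outer = _circle_polygon(c, r)
        gy, gx = np.mgrid[0:n, 0:n]
        d = np.hypot(gy - c[1], gx - c[0])
        ring = (d <= r) & (d >= r - 4)
        img[ring] = 0.55
        img[(d < r - 4)] = np.clip(img[(d < r - 4)] * 0.985, 0, 1)
        annotations.append(Annotation(outer, "inner_artifact"))
    if spec.pen_mark:
        y = rng.uniform(0.1 * n, 0.9 * n)
        x0 = rng.uniform(0.05 * n, 0.35 * n)
        ln = rng.uniform(0.2 * n, 0.4 * n)
        rect = np.array(
            [(x0, y), (x0 + ln, y), (x0 + ln, y + 10), (x0, y + 10)], dtype=float
        )
        m = polygon_mask((n, n), [rect])
        img[m] = (0.1, 0.2, 0.6)  # blue marker
        annotations.append(Annotation(rect, "edge"))
    if spec.stain_residue:
        c = rng.uniform(0.2 * n, 0.8 * n, size=2)
        r = rng.uniform(20, 45)
        gy, gx = np.mgrid[0:n, 0:n]
        d = np.hypot(gy - c[1], gx - c[0])
        smudge = np.clip(1.0 - d / r, 0.0, 1.0) * 0.25
        tint = hsv2rgb(np.array([[[(spec.stain_hue_deg % 360) / 360.0, 0.5, 0.6]]]))[0, 0]
        img = img * (1 - smudge[:, :, None]) + tint * smudge[:, :, None]
        annotations.append(Annotation(_circle_polygon(c, r), "inner_artifact"))

    if spec.blur_fraction > 0:
        r = n * np.sqrt(spec.blur_fraction / np.pi)
        c = rng.uniform(0.2 * n, 0.8 * n, size=2)
        gy, gx = np.mgrid[0:n, 0:n]
        region = np.hypot(gy - c[1], gx - c[0]) <= r
        blurred = ndimage.gaussian_filter(img, sigma=(3.0, 3.0, 0.0))
        img[region] = blurred[region]

    level0 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    levels = [level0]
    spacings = [spec.spacing]
    for _ in range(1, spec.n_levels):
        levels.append(_mean_downsample_rgb(levels[-1]))
        spacings.append(spacings[-1] * 2.0)
    return ImagePyramid(levels, spacings), AnnotationSet(annotations)


def default_dataset_specs(
    n_images: int,
    seed: int,
    canvas: int = 2048,
    with_artifacts: bool = True,
    fatty_every: int = 3,
    stain_hue_deg: float = None,
) -> list:
    """Specs for a homogeneous synthetic dataset.

    Every ``fatty_every``-th slide carries one fatty blob; artifact toggles
    cycle through the four kinds so all six sampling-mask labels occur in
    the dataset.  Hues vary mildly around the chosen stain unless a fixed
    hue is given.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_images):
        hue = (
            stain_hue_deg
            if stain_hue_deg is not None
            else float(rng.uniform(270.0, 330.0))
        )
        specs.append(
            SyntheticSpec(
                canvas=canvas,
                n_blobs=2,
                fatty_fraction=0.5 if (fatty_every and i % fatty_every == fatty_every - 1) else 0.0,
                stain_hue_deg=hue,
                stain_saturation=float(rng.uniform(0.35, 0.55)),
                air_bubble=with_artifacts and i % 4 == 0,
                coverslip_edge=with_artifacts and i % 4 == 1,
                pen_mark=with_artifacts and i % 4 == 2,
                stain_residue=with_artifacts and i % 4 == 3,
                blur_fraction=0.02 if i % 5 == 0 else 0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
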