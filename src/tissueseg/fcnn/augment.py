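"""Patch augmentation: geometry, hue-saturation-brightness color shifts,
contrast, noise and blur.

Steps are applied in a fixed order: mirror, 90-degree rotation, scaling,
hue, saturation, brightness, contrast, additive Gaussian noise, Gaussian
blur.  Geometric steps transform the image and the label patch identically;
photometric steps touch the image only.  The hue shift rotates every color
by the same angle on the hue circle, so pairwise hue distances are
preserved — this is what forces stain-agnostic features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

#: (low, high) parameter ranges; scale/hue/saturation/brightness/contrast
#: are uniform draws, rotation is one of four right angles
RANGES = {
    "scale": (0.75, 1.25),
    "hue": (-1.0, 1.0),
    "saturation": (-0.25, 0.25),
    "brightness": (-0.25, 0.25),
    "contrast": (-0.25, 0.25),
    "noise_sigma": (0.0, 0.05),
    "blur_sigma": (0.0, 1.0),
}


@dataclass(frozen=True)
class AugmentationParams:
    mirror: bool = False
    rotation: int = 0          # degrees, one of 0/90/180/270
    scale: float = 1.0
    hue: float = 0.0           # maps to a shift of hue*180 degrees
    saturation: float = 0.0
    brightness: float = 0.0
    contrast: float = 0.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0

    def validate(self):
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0/90/180/270")
        for name, (lo, hi) in RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside range ({lo}, {hi})")


def random_params(rng: np.random.Generator) -> AugmentationParams:
    return AugmentationParams(
        mirror=bool(rng.integers(2)),
        rotation=int(rng.choice([0, 90, 180, 270])),
        scale=float(rng.uniform(*RANGES["scale"])),
        hue=float(rng.uniform(*RANGES["hue"])),
        saturation=float(rng.uniform(*RANGES["saturation"])),
        brightness=float(rng.uniform(*RANGES["brightness"])),
        contrast=float(rng.uniform(*RANGES["contrast"])),
        noise_sigma=float(rng.uniform(*RANGES["noise_sigma"])),
        blur_sigma=float(rng.uniform(*RANGES["blur_sigma"])),
    )


def scaled_window_px(out_px: int, scale: float) -> int:
    """Side of the source window that resizes to ``out_px`` under ``scale``."""
    return max(1, int(round(out_px * scale)))


def shift_hue(rgb01: np.ndarray, hue: float) -> np.ndarray:
    """Rotate all hues by ``hue * 180`` degrees (hue in (-1, 1))."""
    hsv = rgb2hsv(rgb01)
    hsv[..., 0] = (hsv[..., 0] + hue * 0.5) % 1.0
    return hsv2rgb(hsv)


def augment(patch: np.ndarray, labels: np.ndarray,
            params: AugmentationParams, rng: np.random.Generator = None,
            out_px: int = None) -> tuple:
    """Apply one augmentation draw to an image patch and its label patch.

    ``patch`` is (S, S, 3) uint8 or float in [0, 1]; ``labels`` is (S, S)
    binary.  When ``params.scale != 1`` the input window should measure
    ``scaled_window_px(out_px, scale)`` pixels per side: the scaling step
    resizes it (bilinear image, nearest labels) to ``out_px``, keeping the
    delivered patch size fixed.  Returns float32 image in [0, 1] and uint8
    labels, both ``out_px`` square.
    """
    params.validate()
    img = np.asarray(patch)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    else:
        img = img.astype(np.float32)
    lab = np.asarray(labels)
    if out_px is None:
        out_px = img.shape[0] if params.scale == 1.0 else int(round(img.shape[0] / params.scale))

    # --- geometry (image and labels together) -------------------------
    if params.mirror:
        img = img[:, ::-1]
        lab = lab[:, ::-1]
    k = params.rotation // 90
    if k:
        img = np.rot90(img, k)
        lab = np.rot90(lab, k)
    if img.shape[0] != out_px or img.shape[1] != out_px:
        img = resize(img, (out_px, out_px), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(np.float32)
        lab = resize(lab.astype(np.uint8), (out_px, out_px), order=0,
                     mode="edge", anti_aliasing=False,
                     preserve_range=True).astype(np.uint8)

    # --- photometry (image only) ---------------------------------------
    if params.hue != 0.0 or params.saturation != 0.0 or params.brightness != 0.0:
        hsv = rgb2hsv(np.clip(img, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + params.hue * 0.5) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + params.saturation, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] + params.brightness, 0.0, 1.0)
        img = hsv2rgb(hsv).astype(np.float32)
    if params.contrast != 0.0:
        img = np.clip((img - 0.5) * (1.0 + params.contrast) + 0.5, 0.0, 1.0)
    if params.noise_sigma > 0.0:
        if rng is None:
            raise ValueError("noise augmentation requires an rng")
        img = np.clip(img + rng.normal(0.0, params.noise_sigma, img.shape)
                      .astype(np.float32), 0.0, 1.0)
    if params.blur_sigma > 0.0:
        img = ndimage.gaussian_filter(img, sigma=(params.blur_sigma,
                                                  params.blur_sigma, 0.0))
    return img.astype(np.float32), np.ascontiguousarray(lab, dtype=np.uint8)
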