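# tissueseg

Tissue-versus-background segmentation for multiresolution whole-slide
histopathology images (WSIs).

Whole-slide scanners segment a low-resolution overview of the glass slide
to decide which areas to scan at high magnification; tissue the detector
misses is lost to diagnostics.  Classical detectors (fixed grayscale
thresholds, Otsu's method, edge-based FESI) fail on weakly stained or
fatty tissue and on slide artifacts.  `tissueseg` implements a
resolution-agnostic fully convolutional network (FCNN) for this task,
together with those three classical baselines, the sampling-mask machinery
that trains it, a shared post-processing and region-level evaluation
protocol, and a synthetic pyramidal-slide generator so the entire pipeline
can be developed and tested without access to clinical WSIs.

## The method in brief

A WSI is a pyramid of RGB rasters whose pixel spacing doubles per level.
The FCNN (seven convolutions, three max-pools, softmax; output grid 8×
coarser than its input) is trained on 128×128 patches sampled from
six-label masks — edge, artifacts, background, external margin, internal
margin, tissue — with class weights (1, 1, 1, 1, 5, 1), so the
internal margin (tissue within 125 px of the boundary) is oversampled
5×.  Labels collapse to binary for learning: tissue = {tissue, internal
margin}.  Augmentation includes full-circle hue rotation in HSV space,
which forces stain-agnostic features.  A multi-level variant draws each
patch's source level uniformly from {0.5, 1.0, 2.0, 4.0, 8.0} µm pixel
spacing and therefore segments any of those resolutions with one set of
weights.  At inference the network runs fully convolutionally over a whole
level in overlapping tiles (exactly equal to a single pass), and the
tissue probability map is thresholded at t = 0.8.

Predicted and reference masks are compared by Dice score
2|P∩R|/(|P|+|R|), region sensitivity (a reference region counts as
detected when ≥ 80 % of its area is covered), and false-positive regions
(predicted components with zero reference overlap); method differences
are tested with paired t-tests under Bonferroni correction.  All methods
share one post-processing: regions and holes with equivalent diameter
under 250 µm are removed/filled.

The network itself is implemented in numpy (im2col convolutions, Adam,
He initialization); scipy/scikit-image provide the classical image
operations and tifffile the pyramidal TIFF I/O.

## Worked example

```sh
# 1. render a synthetic slide (pyramidal TIFF + ASAP-style annotation XML)
tissueseg synth --out data --name slide --seed 7

# 2. segment it with a classical method at 2 µm pixel spacing
tissueseg segment --method otsu --spacing 2.0 \
    --input data/slide.tif --output otsu_mask.tif
```

which prints, for example:

```
wrote data/slide.tif (5 levels)
otsu mask at 2 µm -> otsu_mask.tif
```

Training and evaluating the network from Python (the full desk-scale
study: generate slides, train multi-level, calibrate the threshold on the
validation split, score held-out slides; ~7 min on one CPU core):

```python
import numpy as np
from tissueseg.experiments import run_study

study = run_study(seed=2024)
print(study["threshold"])
for spacing, scores in study["level_scores"].items():
    print(spacing, np.round(np.mean(scores), 4))
```

prints

```
0.45
0.5 0.9916
2.0 0.9878
8.0 0.9656
```

— the multi-level network holds its Dice within 0.03 across the 0.5/2/8 µm
levels, and rotating the stain hue of every test slide by 120°
(`study["hue_scores"]`) moves mean Dice by ~0.001: the desk-scale analogue
of resolution-agnostic, stain-agnostic segmentation.  The fixed threshold
degrades on "fatty" fixtures (near-white lobules with thin membranes)
while the network does not, reproducing the failure mode that motivates a
learned detector.

## Layout

| module | contents |
| --- | --- |
| `tissueseg.pyramid` | pyramidal TIFF read/write, level selection by spacing, padded region reads |
| `tissueseg.annotations` | ASAP XML and GeoJSON polygon annotation I/O |
| `tissueseg.masks` | annotation cleanup, pixel-center rasterization, margin labels, binarization, shared post-processing |
| `tissueseg.baselines` | fixed threshold, Otsu, FESI |
| `tissueseg.fcnn` | network, class-weighted patch sampler, augmentation, training loop, tiled inference |
| `tissueseg.evaluate` | Dice, region metrics, paired t-tests, reports |
| `tissueseg.synthetic` | synthetic pyramidal slide generator |
| `tissueseg.experiments` | the desk-scale reference study |
| `tissueseg.cli` | `tissueseg synth / train / segment / evaluate` |

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
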