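# Methods

## Problem and model

Whole-slide scanners must find every piece of tissue on a glass slide from
a low-resolution overview; missed tissue is unrecoverable downstream.
`tissueseg` frames this as binary segmentation of multiresolution RGB
pyramids (pixel spacing doubling per level) into tissue and background, and
implements four segmenters under one shared evaluation protocol:

1. **Fixed threshold** — grayscale (unweighted RGB mean) < *i* = 217, then
   hole filling and morphological closing.
2. **Otsu** — adaptive grayscale threshold minimizing within-class
   variance; the dark class is tissue.
3. **FESI** — foreground extraction from structure information: threshold
   the Gaussian-blurred |Laplacian| at its image mean, median-blur, open,
   flood-fill the background from the point furthest from any foreground,
   then keep only regions whose distance-transform maxima pass the seed
   rule (value > 100 px, or within 100 px of an accepted seed).
4. **FCNN** — a seven-convolution fully convolutional classifier
   (5×5×16, pool, 5×5×32, pool, 3×3×64, pool, 3×3×64, 3×3×1024, 1×1×512,
   1×1×2-softmax; ReLU elsewhere; ~1.19 M parameters; receptive field
   60 px; output grid 8× coarser than the input).

The FCNN trains on 128 px patches drawn from six-label sampling masks
(edge, artifacts, background, external margin, internal margin, tissue)
with class weights 1,1,1,1,5,1 — the internal margin (the tissue side of
the boundary) is oversampled because the boundary is where segmenters
disagree.  Labels collapse to binary for the loss: tissue = {tissue,
internal margin}.  A *multi-level* model draws each patch's source level
uniformly from {0.5, 1.0, 2.0, 4.0, 8.0} µm, which makes a single network
usable across resolutions.

## Reference masks

Polygon annotations (four classes: tissue, background = holes, edge
artifacts, inner artifacts) are normalized before rasterization: tissue
regions with equivalent-area diameter (2·√(area/π)) under 250 µm are
removed ("smaller than" is strict), regions closer than 50 µm are merged
(morphological closing via ±25 µm polygon buffers), and holes under 250 µm
are filled.  Removal runs first, then merging, then hole filling.
Rasterization uses the pixel-center even-odd rule (a pixel belongs to a
polygon iff its center is inside), implemented as a scanline directly
because the library polygon fills available here (PIL, skimage.draw) use
different boundary conventions; overlapping classes paint in the order
edge < inner artifact < tissue, with explicitly annotated background last,
since those polygons *are* the annotated holes.  Margin bands are exact
Euclidean distance-transform bands (≤ 125 px) at the rasterized level;
internal margins measure distance to the background label only, so
artifact-adjacent tissue is not margin.

All outputs — classical and neural alike — pass the same post-processing:
remove 8-connected foreground regions and fill 4-connected enclosed holes
with equivalent diameter under 250 µm.  The operation is idempotent.

## Training procedure

He-initialized weights, Adam, categorical cross entropy, L2 weight
λ = 10⁻⁵.  Full-scale defaults mirror the published recipe: 128 px patches,
batch 32, 25 600 training / 6 400 validation iterations per epoch, initial
learning rate 10⁻⁴ halved after every 4 consecutive epochs without
validation-accuracy improvement (> 10⁻⁴), stop after 16; the halved rate is
kept after later improvements.  The best-validation model is returned.
Augmentation per patch, in order: horizontal mirror; 90° rotations; scale
z ∈ (0.75, 1.25) — the sampler extracts a round(128·z) px window that is
resized back to 128 (bilinear image, nearest labels); hue shift h·180° for
h ∈ (−1, 1), which spans the full hue circle and preserves pairwise hue
distances (this is what forces stain-agnostic features); saturation and
brightness offsets ± 0.25 in HSV; contrast (x−½)(1+c)+½, c ∈ (−0.25, 0.25);
additive Gaussian noise σ ∈ (0, 0.05); Gaussian blur σ ∈ (0, 1) — all on
[0, 1] intensities, clipped.

Dense targets: the binary label patch pooled 8× to the output grid, under
one of three rules.  `any` (a cell is tissue if any pixel is) maximizes
sensitivity but dilates the boundary by up to 7 px; `majority` (≥ 50 % of
the cell) places it without bias; `fraction` trains on the cell's exact
tissue coverage as a soft label.  At clinical-slide scale the rules are
nearly indistinguishable — regions span thousands of output cells — but at
fixture scale (regions tens of cells wide) the choice is decisive: the
8 µm-level Dice of a *perfect* hard-label predictor is capped near 0.92 by
the coarse grid, whereas a fraction-trained model's interpolated
probability map encodes the boundary with sub-cell precision and raises
that ceiling to ~0.98.  The desk-scale study therefore uses `fraction`;
`any` remains the constructor default for sensitivity-critical use.

Inference applies the network fully convolutionally in overlapping tiles
(halo ≥ half the 60 px receptive field, all offsets multiples of 8), so
tiled output equals a single whole-image pass exactly; the probability map
is upsampled 8× (nearest by default; bilinear as an option) and
thresholded at t = 0.8, inclusive.  t is a calibrated constant: it was
chosen — and on new data should be re-chosen — by maximizing mean Dice on
a validation split.  The desk-scale study does exactly that over a 0.05
grid (it lands near 0.45–0.6; soft-target probabilities are less saturated
than hard-target ones, so their operating point sits lower) and evaluates
with bilinear upsampling, since at 64–128 px levels the 8 px blocks of
nearest upsampling dominate the boundary error.  A shift-and-stitch option
(`refine`) interleaves shifted passes to cut the map pitch below 8 px; it
helps hard-label models but is unnecessary once soft targets carry
sub-cell information, and the study leaves it off.

## Synthetic study conditions

The generator renders pyramidal slides (2048 px canvas at 0.5 µm, five
levels to 8 µm) with polygon ground truth: near-white background
(N(245, 2) gray), star-shaped stained blobs (560–800 px ≈ 280–400 µm, so
they survive cleanup and remain resolvable at 8 µm) textured with
band-limited noise and nucleus-like dots, "fatty" blobs as Voronoi-edge
membranes around near-white lobules, out-of-focus patches, and four
artifact kinds (air bubble, coverslip edge, pen mark, stain residue)
annotated with their proper classes.  Stain hue is a free parameter.
Everything derives from one seed; generation is bit-reproducible.

What the generator does *not* emulate: real nuclear/stromal morphology,
scanner noise and compression, stain co-localization physics, tissue
debris continua.  Passing tests therefore demonstrate that the pipeline
is implemented correctly and behaves as the method intends on images with
the right difficulty axes (near-white fat, unseen hues, artifacts) — not
clinical performance.

The desk-scale study: 10 development slides (8 train / 2 validation) and 4
held-out test slides, multi-level training over all five spacings with
64 px patches (the smallest 8-aligned patch covering the 60 px receptive
field), batch 8, up to 18 epochs × 120 iterations (20 validation
iterations), Adam at 10⁻³ — a larger step compensating the short schedule
— with fraction targets, followed by threshold calibration on the
validation slides.  Evaluation: post-processed Dice at 0.5/2/8 µm against
rasterized ground truth, plus the same test slides re-rendered with every
stain hue rotated 120° as the unseen-stain probe.  FESI's seed constants scale to 25 px for
these fixtures: 100 px assumes gigapixel slides, while fixture blobs have
inscribed-disc radii of 35–100 px at 2 µm (the method's constants are in
pixels of the evaluated level, one of its documented weaknesses).

## Numerical choices and edge cases

- Level selection: minimize |spacing − target|; ties to the finer level.
- Region reads pad out-of-extent pixels with white (255).
- Mask pyramids downsample by 2×2 majority, ties → tissue, partial edge
  blocks vote over their real pixels only.
- Dice of two empty masks is 1.0; one empty, 0.0.
- Sensitivity with no reference regions is NaN, excluded from aggregates.
- Pixels equal to a grayscale threshold are background; probability
  exactly at t = 0.8 is tissue.
- Otsu on a single-valued histogram raises; optimum ties resolve to the
  lowest level.
- Paired t-tests with zero-variance differences report p at the machine
  epsilon bound with a degenerate flag rather than dividing by zero;
  Bonferroni multiplies by the number of method pairs, capped at 1.
- Missing TIFF resolution tags require an explicit `pixel_spacing_um`.
- Morphological closing pads before dilating so image borders are not
  eroded.
- Written TIFFs use zlib/deflate compression (read side also accepts LZW
  and JPEG).

## Known limitations

- The FCNN runs on CPU numpy; throughput is ~6 batch-updates/s at 64 px
  patches, batch 8 (one desk-scale training run takes ~6 min on one
  core) — fine for the study, far from production training.
- FESI fidelity: the original's exact kernels are unpublished; kernel
  sizes here are declared choices exposed in `FesiParams`, and maxima
  iteration visits each distance-transform local maximum once, in
  decreasing order.
- The annotation-cleanup merge uses polygon buffers; buffer tessellation
  means idempotence holds geometrically (region count, raster), not
  vertex-for-vertex.
- Validation accuracy is pixel-level on the output grid; the alternative
  patch-level reading is not implemented.
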