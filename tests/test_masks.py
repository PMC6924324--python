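"""Annotation cleanup, rasterization, margins, binarization, post-processing."""

import math

import numpy as np
import pytest
from scipy import ndimage

from tissueseg.core import (
    ARTIFACTS,
    BACKGROUND,
    EDGE,
    EXTERNAL_MARGIN,
    INTERNAL_MARGIN,
    TISSUE,
    Annotation,
    AnnotationSet,
    BinaryMask,
    LevelRef,
    SamplingMask,
    margin_physical_um,
)
from tissueseg.masks import (
    add_margins,
    clean_annotations,
    min_region_area_px,
    polygon_mask,
    postprocess,
    rasterize,
    to_binary,
)


def circle(cx, cy, r, n=128):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def square(x0, y0, side):
    return np.array(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
        dtype=float,
    )


class TestCleanAnnotations:
    def test_small_disc_removed(self):
        # 240 µm diameter at 1 µm/px: below the 250 µm floor
        ann = AnnotationSet([Annotation(circle(500, 500, 120), "tissue")])
        assert len(clean_annotations(ann, 1.0).by_label("tissue")) == 0

    def test_big_disc_retained(self):
        ann = AnnotationSet([Annotation(circle(500, 500, 130), "tissue")])
        out = clean_annotations(ann, 1.0).by_label("tissue")
        assert len(out) == 1

    @pytest.mark.parametrize("gap,expected_regions", [(40, 1), (60, 2)])
    def test_gap_merging(self, gap, expected_regions):
        # two 300 px squares at 1 µm/px, separated horizontally by `gap` µm
        a = square(100, 100, 300)
        b = square(400 + gap, 100, 300)
        ann = AnnotationSet([Annotation(a, "tissue"), Annotation(b, "tissue")])
        out = clean_annotations(ann, 1.0).by_label("tissue")
        assert len(out) == expected_regions
        if expected_regions == 1:
            import shapely.geometry as gm

            merged = gm.Polygon(out[0].exterior)
            assert merged.area >= 2 * 300 * 300

    def test_merge_agrees_with_pixel_closing(self):
        # oracle: rasterize, then binary closing with a 25 px disc
        gap = 40
        a = square(50, 50, 300)
        b = square(350 + gap, 50, 300)
        ann = AnnotationSet([Annotation(a, "tissue"), Annotation(b, "tissue")])
        cleaned = clean_annotations(ann, 1.0)
        level = LevelRef(0, 1.0)
        vector_raster = rasterize(cleaned, (450, 800), level) == TISSUE
        n_vec = ndimage.label(vector_raster, np.ones((3, 3)))[1]

        raw = rasterize(ann, (450, 800), level) == TISSUE
        yy, xx = np.mgrid[-25:26, -25:26]
        disc = (yy**2 + xx**2) <= 25**2
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(raw, disc), disc, border_value=1
        )
        n_pix = ndimage.label(closed, np.ones((3, 3)))[1]
        assert n_vec == n_pix == 1

    def test_small_hole_filled_large_hole_kept(self):
        outer = circle(600, 600, 400)
        small_hole = circle(450, 450, 100)   # 200 µm diameter -> filled
        big_hole = circle(750, 750, 150)     # 300 µm diameter -> kept
        ann = AnnotationSet([
            Annotation(outer, "tissue"),
            Annotation(small_hole, "background"),
            Annotation(big_hole, "background"),
        ])
        out = clean_annotations(ann, 1.0).by_label("tissue")
        assert len(out) == 1
        assert len(out[0].interiors) == 1

    def test_idempotent(self, small_annotations):
        once = clean_annotations(small_annotations, 2.0)
        twice = clean_annotations(once, 2.0)
        assert len(once.by_label("tissue")) == len(twice.by_label("tissue"))
        lv = LevelRef(0, 2.0)
        r1 = rasterize(once, (512, 512), lv) == TISSUE
        r2 = rasterize(twice, (512, 512), lv) == TISSUE
        assert (r1 ^ r2).mean() < 1e-3  # identical up to buffer vertex jitter

    def test_empty_set_passes_through(self):
        out = clean_annotations(AnnotationSet([]), 1.0)
        assert len(out) == 0


def brute_point_in_polygon(shape, rings, scale=1.0):
    """Per-pixel even-odd crossing test at pixel centers (the declared rule)."""
    h, w = shape
    out = np.zeros((h, w), bool)
    rr = [np.asarray(r, float) / scale for r in rings]
    for y in range(h):
        for x in range(w):
            px, py = x + 0.5, y + 0.5
            inside = False
            for v in rr:
                n = len(v)
                for i in range(n):
                    x1, y1 = v[i]
                    x2, y2 = v[(i + 1) % n]
                    if (y1 <= py < y2) or (y2 <= py < y1):
                        xc = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                        if xc > px:
                            inside = not inside
            out[y, x] = inside
    return out


class TestRasterize:
    def test_empty_is_all_background(self):
        lv = LevelRef(0, 1.0)
        r = rasterize(AnnotationSet([]), (32, 32), lv)
        assert (r == BACKGROUND).all()

    def test_axis_aligned_square_pixel_count(self):
        lv = LevelRef(0, 1.0)
        ann = AnnotationSet([Annotation(square(0, 0, 10), "tissue")])
        r = rasterize(ann, (20, 20), lv)
        assert (r == TISSUE).sum() == 100

    def test_annotated_hole_is_background(self):
        lv = LevelRef(0, 1.0)
        ann = AnnotationSet([
            Annotation(square(0, 0, 40), "tissue"),
            Annotation(square(10, 10, 10), "background"),
        ])
        r = rasterize(ann, (50, 50), lv)
        assert (r[12:18, 12:18] == BACKGROUND).all()
        assert (r == TISSUE).sum() == 40 * 40 - 10 * 10

    def test_overlap_priority_tissue_over_artifacts(self):
        lv = LevelRef(0, 1.0)
        ann = AnnotationSet([
            Annotation(square(0, 0, 20), "tissue"),
            Annotation(square(10, 0, 20), "inner_artifact"),
            Annotation(square(0, 10, 20), "edge"),
        ])
        r = rasterize(ann, (40, 40), lv)
        assert (r[0:20, 0:20] == TISSUE).all()
        assert (r[0:10, 20:30] == ARTIFACTS).all()
        assert (r[20:30, 0:20] == EDGE).all()

    def test_matches_pointwise_oracle(self, rng):
        poly = circle(20, 22, 14, n=17) + rng.normal(0, 2.0, (17, 2))
        hole = circle(20, 22, 5, n=9)
        fast = polygon_mask((44, 44), [poly, hole])
        brute = brute_point_in_polygon((44, 44), [poly, hole])
        assert np.array_equal(fast, brute)

    def test_scale_halves_coordinates(self):
        lv = LevelRef(1, 2.0)
        ann = AnnotationSet([Annotation(square(0, 0, 20), "tissue")])
        r = rasterize(ann, (20, 20), lv)  # scale 2 -> 10x10 px
        assert (r == TISSUE).sum() == 100


class TestMargins:
    def test_half_plane_band_widths(self):
        # tissue occupies columns 0..199; margins must be exactly 125 px wide
        lv = LevelRef(0, 1.0)
        raster = np.full((40, 600), BACKGROUND, np.uint8)
        raster[:, :200] = TISSUE
        mask = add_margins(raster, lv).data
        assert (mask[:, 200:325] == EXTERNAL_MARGIN).all()
        assert (mask[:, 325:] == BACKGROUND).all()
        assert (mask[:, 75:200] == INTERNAL_MARGIN).all()
        assert (mask[:, :75] == TISSUE).all()

    def test_all_background_unchanged(self):
        lv = LevelRef(0, 1.0)
        raster = np.full((64, 64), BACKGROUND, np.uint8)
        assert (add_margins(raster, lv).data == BACKGROUND).all()

    @pytest.mark.parametrize("spacing,width_um", [(0.5, 62.5), (2.0, 250.0),
                                                  (8.0, 1000.0)])
    def test_margin_physical_width(self, spacing, width_um):
        assert margin_physical_um(spacing) == pytest.approx(width_um)

    def test_matches_bruteforce_distances(self, rng):
        lv = LevelRef(0, 1.0)
        raster = np.full((72, 72), BACKGROUND, np.uint8)
        blob = polygon_mask((72, 72), [circle(30, 35, 14, n=33)])
        raster[blob] = TISSUE
        raster[60:70, 60:70] = ARTIFACTS
        margin = 9
        got = add_margins(raster, lv, margin_px=margin).data

        tissue_pts = np.argwhere(raster == TISSUE)
        bg_pts = np.argwhere(raster == BACKGROUND)
        exp = raster.copy()
        for y, x in bg_pts:
            d2 = ((tissue_pts - (y, x)) ** 2).sum(axis=1).min()
            if d2 <= margin**2:
                exp[y, x] = EXTERNAL_MARGIN
        for y, x in tissue_pts:
            d2 = ((bg_pts - (y, x)) ** 2).sum(axis=1).min()
            if d2 <= margin**2:
                exp[y, x] = INTERNAL_MARGIN
        assert np.array_equal(got, exp)

    def test_binarization_conserves_tissue(self, rng):
        # margins re-label but never move a pixel across the tissue boundary
        lv = LevelRef(0, 1.0)
        raster = rng.choice([EDGE, ARTIFACTS, BACKGROUND, TISSUE],
                            size=(96, 96)).astype(np.uint8)
        binary = to_binary(add_margins(raster, lv, margin_px=7)).data
        assert np.array_equal(binary, (raster == TISSUE).astype(np.uint8))


class TestToBinary:
    def test_table_card(self):
        lv = LevelRef(0, 1.0)
        card = np.array([[EDGE, ARTIFACTS, BACKGROUND,
                          EXTERNAL_MARGIN, INTERNAL_MARGIN, TISSUE]], np.uint8)
        out = to_binary(SamplingMask(card, lv))
        assert out.data.tolist() == [[0, 0, 0, 0, 1, 1]]

    def test_unknown_label_rejected(self):
        lv = LevelRef(0, 1.0)
        mask = SamplingMask(np.full((4, 4), TISSUE, np.uint8), lv)
        mask.data[0, 0] = 9  # corrupt after validation
        with pytest.raises(ValueError):
            to_binary(mask)


class TestPostprocess:
    def test_small_region_removed_large_kept(self):
        data = np.zeros((600, 600), np.uint8)
        data[polygon_mask((600, 600), [circle(100, 100, 100)])] = 1  # 200 µm
        data[polygon_mask((600, 600), [circle(400, 400, 140)])] = 1  # 280 µm
        out = postprocess(BinaryMask(data, 1.0))
        assert out.data[100, 100] == 0
        assert out.data[400, 400] == 1

    def test_small_hole_filled_large_hole_kept(self):
        data = np.ones((900, 900), np.uint8)
        data[polygon_mask((900, 900), [circle(200, 200, 100)])] = 0  # filled
        data[polygon_mask((900, 900), [circle(600, 600, 140)])] = 0  # kept
        out = postprocess(BinaryMask(data, 1.0))
        assert out.data[200, 200] == 1
        assert out.data[600, 600] == 0

    def test_border_background_is_not_a_hole(self):
        data = np.ones((400, 400), np.uint8)
        data[:10] = 0  # touches the border: stays open
        out = postprocess(BinaryMask(data, 1.0))
        assert (out.data[:5] == 0).all()

    def test_idempotent(self, rng):
        blobs = (ndimage.gaussian_filter(
            rng.standard_normal((300, 300)), 12) > 0.12).astype(np.uint8)
        once = postprocess(BinaryMask(blobs, 2.0))
        twice = postprocess(once)
        assert np.array_equal(once.data, twice.data)

    def test_diameter_equals_area_threshold(self):
        # area threshold pi * (125 µm)^2 at 1 µm/px = 49087.38 px
        thr = min_region_area_px(1.0)
        assert thr == pytest.approx(math.pi * 125**2)
        small = np.zeros((400, 400), np.uint8)
        small[10:170, 10:10 + 306] = 1   # 48960 px < thr -> removed
        big = np.zeros((400, 400), np.uint8)
        big[10:170, 10:10 + 307] = 1     # 49120 px >= thr -> kept
        assert postprocess(BinaryMask(small, 1.0)).data.sum() == 0
        assert postprocess(BinaryMask(big, 1.0)).data.sum() == 160 * 307
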