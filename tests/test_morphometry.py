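"""Morphometry pipeline: calibration through replicate summaries."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from rflesion import morphometry as morph
from rflesion import synthetic as syn
from rflesion.morphometry import (
    CalibrationError,
    LesionRegion,
    RegionError,
    calibrate,
    fill_holes,
    measure_region,
    threshold_lesion,
    to_grayscale,
)


def brute_force_moments(mask):
    """Per-pixel loop computation of area, centroid, and ellipse-equivalent
    axes/orientation from second central moments (independent oracle)."""
    coords = np.argwhere(mask).astype(float)
    n = len(coords)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    cov = d.T @ d / n
    evals, evecs = np.linalg.eigh(cov)
    major, minor = 4 * np.sqrt(evals[1]), 4 * np.sqrt(evals[0])
    v = evecs[:, 1]  # (row, col) direction of the major axis
    orientation = np.degrees(np.arctan2(v[1], v[0]))
    if orientation > 90:
        orientation -= 180
    elif orientation <= -90:
        orientation += 180
    return n, centroid, major, minor, orientation


def disk_mask(r_mm, mm_per_pixel=0.05, center_mm=(5.0, 5.0), extent_mm=10.0):
    spec = syn.LesionSpec("circle", r_mm, r_mm, center_mm=center_mm)
    n = int(extent_mm / mm_per_pixel)
    return syn.rasterize_top_mask(spec, (n, n), mm_per_pixel)


class TestCalibrate:
    def test_two_point_scale(self):
        ci = calibrate(np.zeros((10, 10)), points=((0, 0), (0, 100)), separation_mm=5.0)
        assert ci.mm_per_pixel == pytest.approx(0.05)

    def test_explicit_scale_passthrough(self):
        assert calibrate(np.zeros((4, 4)), 0.05).mm_per_pixel == 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"points": ((3, 3), (3, 3)), "separation_mm": 5.0},
            {"mm_per_pixel": 0.0},
            {"mm_per_pixel": -1.0},
            {},
        ],
    )
    def test_unresolvable_scale_is_fatal(self, kwargs):
        with pytest.raises(CalibrationError):
            calibrate(np.zeros((4, 4)), **kwargs)


class TestGrayscale:
    def test_pure_white_and_black(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = 255
        gray = to_grayscale(img)
        assert gray[0, 0] == pytest.approx(1.0)
        assert gray[1, 1] == pytest.approx(0.0)

    def test_rec601_weights_before_normalization(self):
        img = np.zeros((1, 3, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        img[0, 1] = (0, 255, 0)
        img[0, 2] = (0, 0, 255)
        gray = to_grayscale(img, normalize=False)
        assert gray[0] == pytest.approx([0.299, 0.587, 0.114])

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((0, 0)))


class TestThreshold:
    def test_uniform_midgray_is_all_foreground(self, caplog):
        with caplog.at_level(logging.WARNING):
            mask = threshold_lesion(np.full((5, 5), 0.5), 0.40)
        assert mask.all()
        assert "degenerate" in caplog.text

    def test_linear_ramp_boundary_at_isoline(self):
        # intensity ramps 0 -> 1 over 20 px: the 40% isoline is at column 8
        ramp = np.tile(np.linspace(0, 1, 21), (5, 1))
        mask = threshold_lesion(ramp, 0.40)
        first_fg = np.argmax(mask[0])
        assert abs(first_fg - 8) <= 1

    def test_hard_edge_mask_recovered_exactly(self):
        core = disk_mask(2.0)
        gray = np.where(core, 1.0, 0.1)
        assert np.array_equal(threshold_lesion(gray, 0.40), core)

    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.9), st.floats(0.05, 0.9))
    @settings(max_examples=40, deadline=None)
    def test_raising_threshold_never_grows_area(self, seed, c1, c2):
        img = np.random.default_rng(seed).uniform(size=(30, 30))
        lo, hi = sorted((c1, c2))
        assert threshold_lesion(img, hi).sum() <= threshold_lesion(img, lo).sum()


class TestFillHoles:
    def test_annulus_becomes_disk(self):
        outer, inner = disk_mask(3.0), disk_mask(1.5)
        annulus = outer & ~inner
        assert np.array_equal(fill_holes(annulus), outer)

    def test_idempotent_on_solid_shapes(self):
        m = disk_mask(2.5)
        once = fill_holes(m)
        assert np.array_equal(once, m)
        assert np.array_equal(fill_holes(once), once)

    def test_nested_holes_match_border_flood_fill_oracle(self):
        m = disk_mask(3.0, mm_per_pixel=0.1)
        m[20:24, 20:24] = False
        m[40:43, 30:33] = False
        filled = fill_holes(m)
        # oracle: everything not reachable from the border background
        bg = ~m
        labels, _ = ndimage.label(bg)
        border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
        reachable = np.isin(labels, sorted(border_labels - {0}))
        oracle = ~(bg & reachable)
        assert np.array_equal(filled, oracle)
        assert filled.sum() >= m.sum()


class TestMeasureRegion:
    def test_disk_descriptors(self):
        region = measure_region(disk_mask(3.0), 0.05)
        assert region.area_mm2 == pytest.approx(np.pi * 9, rel=0.01)
        assert region.major_axis_mm / region.minor_axis_mm <= 1.02

    def test_axis_aligned_ellipse_axes(self):
        spec = syn.LesionSpec("ellipse", 4, 2, center_mm=(6, 6))
        mask = syn.rasterize_top_mask(spec, (240, 240), 0.05)
        region = measure_region(mask, 0.05)
        assert region.major_axis_mm == pytest.approx(8.0, rel=0.02)
        assert region.minor_axis_mm == pytest.approx(4.0, rel=0.02)
        assert abs(region.orientation_deg) < 2.0

    def test_single_pixel_area(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert measure_region(mask, 0.05).area_mm2 == pytest.approx(0.0025)

    def test_wrong_component_count_is_fatal(self):
        mask = np.zeros((10, 10), dtype=bool)
        with pytest.raises(RegionError, match="0"):
            measure_region(mask, 0.05)
        mask[1, 1] = mask[8, 8] = True
        with pytest.raises(RegionError, match="2"):
            measure_region(mask, 0.05)

    def test_moments_match_brute_force_oracle(self, rng):
        for _ in range(25):
            a = rng.uniform(1.0, 4.0)
            b = rng.uniform(0.5, a)
            spec = syn.LesionSpec(
                "ellipse", a, b, center_mm=(5.5, 5.5),
                orientation_deg=float(rng.uniform(-80, 80)),
            )
            mask = syn.rasterize_top_mask(spec, (110, 110), 0.1)
            region = measure_region(mask, 0.1)
            n, centroid, major, minor, orient = brute_force_moments(mask)
            assert region.area_mm2 == pytest.approx(n * 0.01, rel=1e-12)
            assert region.centroid_mm == pytest.approx(tuple((centroid + 0.5) * 0.1), abs=1e-9)
            assert region.major_axis_mm == pytest.approx(major * 0.1, rel=1e-9)
            assert region.minor_axis_mm == pytest.approx(minor * 0.1, rel=1e-9)
            assert region.orientation_deg == pytest.approx(orient, abs=1e-6)


class TestAlign:
    def test_tilted_ellipse_becomes_vertical(self):
        spec = syn.LesionSpec("ellipse", 4, 2, center_mm=(8, 8), orientation_deg=37)
        mask = syn.rasterize_top_mask(spec, (320, 320), 0.05)
        region = measure_region(mask, 0.05)
        aligned = morph.align_major_axis(region)
        assert abs(aligned.orientation_deg) < 1.0
        assert aligned.area_mm2 == pytest.approx(region.area_mm2, rel=0.01)
        # rotation is about the canvas centre: the centroid's distance from
        # it is preserved to about a pixel
        def offset(reg):
            return np.hypot(
                reg.centroid_mm[0] - reg.mask.shape[0] * 0.05 / 2,
                reg.centroid_mm[1] - reg.mask.shape[1] * 0.05 / 2,
            )
        assert offset(aligned) == pytest.approx(offset(region), abs=2 * 0.05)

    def test_idempotent(self):
        spec = syn.LesionSpec("ellipse", 3, 1.5, center_mm=(6, 6), orientation_deg=-24)
        mask = syn.rasterize_top_mask(spec, (240, 240), 0.05)
        once = morph.align_major_axis(measure_region(mask, 0.05))
        twice = morph.align_major_axis(once)
        assert twice.area_mm2 == pytest.approx(once.area_mm2, rel=0.01)
        assert abs(twice.orientation_deg) < 1.0

    def test_already_vertical_is_identity(self):
        spec = syn.LesionSpec("ellipse", 3, 1.5, center_mm=(6, 6))
        mask = syn.rasterize_top_mask(spec, (240, 240), 0.05)
        region = measure_region(mask, 0.05)
        assert morph.align_major_axis(region) is region


class TestDepth:
    def test_constructed_depth_recovered(self):
        spec = syn.LesionSpec("circle", 3, 3, depth_mm=5.0)
        frame = syn.generate_bisected_view(spec, 0.05, 0.0, seed=0)
        d = morph.measure_depth(calibrate(frame.image, 0.05, view="bisected"))
        assert d.max_depth_mm == pytest.approx(5.0, abs=0.1)

    def test_deepest_reported_condition_recovered(self):
        spec = syn.LesionSpec("circle", 3.5, 3.5, depth_mm=7.53)
        frame = syn.generate_bisected_view(spec, 0.05, 0.0, seed=0)
        d = morph.measure_depth(calibrate(frame.image, 0.05, view="bisected"))
        assert d.max_depth_mm == pytest.approx(7.53, abs=0.1)

    def test_lesion_above_surface_gives_zero_depth(self, caplog):
        img = np.full((200, 200), syn.SALINE_LEVEL, dtype=np.uint8)
        img[120:, :] = syn.TISSUE_LEVEL  # tissue surface at row 120
        img[20:40, 80:120] = syn.CORE_LEVEL  # bright artefact in the saline
        with caplog.at_level(logging.WARNING):
            d = morph.measure_depth(calibrate(img, 0.05, view="bisected"))
        assert d.max_depth_mm == 0.0
        assert "depth 0" in caplog.text

    def test_top_view_rejected(self):
        with pytest.raises(ValueError, match="bisected"):
            morph.measure_depth(calibrate(np.zeros((5, 5)), 0.05, view="top"))


class TestClassify:
    def _aligned_region(self, spec, mm_per_pixel=0.05, frame=320):
        mask = syn.rasterize_top_mask(spec, (frame, frame), mm_per_pixel)
        return morph.align_major_axis(measure_region(mask, mm_per_pixel))

    def test_circle(self):
        spec = syn.LesionSpec("circle", 3, 3, center_mm=(8, 8))
        assert morph.classify_morphology(self._aligned_region(spec)) == "circle"

    def test_symmetric_ellipse(self):
        spec = syn.LesionSpec("ellipse", 4, 2, center_mm=(8, 8))
        assert morph.classify_morphology(self._aligned_region(spec)) == "ellipse"

    def test_egg_curve_asymmetry_matches_analytic_value(self):
        # half-area asymmetry about the extent midpoint is 2*ovality/(3*pi)
        spec = syn.LesionSpec("oval", 4, 2.5, 0.4, center_mm=(8, 8))
        region = self._aligned_region(spec)
        rows = np.nonzero(region.mask)[0]
        mid = (rows.min() + rows.max()) / 2
        asym = abs(int((rows < mid).sum()) - int((rows > mid).sum())) / rows.size
        assert asym == pytest.approx(2 * 0.4 / (3 * np.pi), abs=0.01)
        assert morph.classify_morphology(region) == "oval"


class TestSummaries:
    def _fake_region(self, area, mask=None):
        if mask is None:
            mask = np.ones((3, 3), dtype=bool)
        return LesionRegion(mask, 0.05, (0, 0), 1.0, 1.0, 0.0, area)

    def test_identical_replicates_have_zero_sd(self):
        regions = [self._fake_region(12.5) for _ in range(6)]
        s = morph.summarize_replicates(regions)
        assert s.n == 6
        assert s.mean_area_mm2 == pytest.approx(12.5)
        assert s.sd_area_mm2 == 0.0
        assert s.mean_mask.max() == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        s = morph.summarize_replicates([self._fake_region(10.0), self._fake_region(20.0)])
        assert s.mean_area_mm2 == pytest.approx(15.0)
        assert s.sd_area_mm2 == pytest.approx(7.0710678, rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            morph.summarize_replicates([])

    def test_low_noise_panel_recovers_reported_cell_mean(self, area_table):
        tops, cuts = syn.make_condition_panel(0, 2, n=6, seed=202, noise_sd=2.0,
                                              border_width_mm=0.2)
        regions, depths = [], []
        for t, c in zip(tops, cuts):
            regions += morph.measure_top_frame(calibrate(t.image, t.mm_per_pixel))
            depths.append(morph.measure_depth(calibrate(c.image, c.mm_per_pixel, view="bisected")))
        s = morph.summarize_replicates(regions, depths)
        cell = area_table.cell(0, 2)
        assert s.n == 6
        assert abs(s.mean_area_mm2 - cell.mean) <= 3 * cell.sd
        assert s.mean_mask.max() <= 1.0


class TestResolutionRobustness:
    def test_mm_area_stable_across_pixel_scales(self):
        spec = syn.LesionSpec("oval", 3.5, 2.2, 0.4, center_mm=(8, 8), orientation_deg=15)
        areas = []
        for mmpp in (0.05, 0.025):
            mask = syn.rasterize_top_mask(spec, (int(16 / mmpp),) * 2, mmpp)
            areas.append(measure_region(mask, mmpp).area_mm2)
        assert abs(areas[0] - areas[1]) / areas[1] < 0.02


def test_segmentation_counts_and_ordering():
    specs = [
        syn.LesionSpec("circle", 2, 2, center_mm=(5, 5)),
        syn.LesionSpec("circle", 2, 2, center_mm=(5, 12)),
        syn.LesionSpec("circle", 2, 2, center_mm=(12, 5)),
    ]
    frame = syn.generate_top_view(specs, 0.05, 0.0, seed=0, frame_shape=(340, 340))
    subs = morph.segment_lesions(calibrate(frame.image, 0.05))
    assert len(subs) == 3
    # speck below the minimum-area filter disappears
    img = frame.image.copy()
    img[300:302, 300:302] = 230
    subs2 = morph.segment_lesions(calibrate(img, 0.05), min_area_mm2=1.0)
    assert len(subs2) == 3


def test_touching_lesions_merge_into_one_candidate():
    # documented limitation: contiguous lesions form a single component
    specs = [syn.LesionSpec("circle", 2, 2, center_mm=(6, 6))]
    frame = syn.generate_top_view(specs, 0.05, 0.0, seed=0, frame_shape=(300, 300))
    img = frame.image.copy()
    shifted = np.roll(img, 70, axis=1)
    merged = np.maximum(img, shifted)
    mask = merged >= 0.4 * 255
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), int))
    assert nlab == 1  # oracle on the composed mask
    subs = morph.segment_lesions(calibrate(merged, 0.05))
    assert len(subs) == 1
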