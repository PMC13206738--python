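"""Threshold segmentation, region metrics, hemifields, repeatability."""

import math

import numpy as np
import pytest

from vitreoquant.imaging import NormalizedImage
from vitreoquant.quantify import (
    DEFAULT_THRESHOLDS,
    EyeBoundary,
    FluorescenceRegion,
    area_percent,
    extract_region,
    fit_diffusivity,
    hemifield_fractions,
    measure_eye,
    radius_centroid,
    radius_feret,
    repeatability_audit,
    sweep_thresholds,
)

# ---------------------------------------------------------------------------
# independent oracles


def flood_fill_components(mask):
    """8-connected components by iterative flood fill (independent oracle)."""
    visited = np.zeros_like(mask, dtype=bool)
    components = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack, pixels = [start], []
        visited[start] = True
        while stack:
            r, c = stack.pop()
            pixels.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not visited[rr, cc]
                    ):
                        visited[rr, cc] = True
                        stack.append((rr, cc))
        components.append(pixels)
    return components


def oracle_largest_component(mask, anchor_xy):
    """Largest component with the documented tie-breaks, as a mask."""
    comps = flood_fill_components(mask)
    if not comps:
        return np.zeros_like(mask, dtype=bool)

    def key(pixels):
        rs = np.array([p[0] for p in pixels], dtype=float)
        cs = np.array([p[1] for p in pixels], dtype=float)
        dist = math.hypot(cs.mean() - anchor_xy[0], rs.mean() - anchor_xy[1])
        first = min(r * mask.shape[1] + c for r, c in pixels)
        return (-len(pixels), dist, first)

    best = min(comps, key=key)
    out = np.zeros_like(mask, dtype=bool)
    for r, c in best:
        out[r, c] = True
    return out


def all_pairs_feret(mask, scale):
    """O(n^2) all-pairs maximum distance between lit pixel centers."""
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 2:
        return 0.0
    best = 0.0
    for i in range(len(pts)):
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        if d.size:
            best = max(best, d.max())
    return best * scale / 2.0


def make_norm(pixels):
    return NormalizedImage(pixels=pixels.astype(np.uint8), source="unit")


# ---------------------------------------------------------------------------


class TestSweep:
    def test_default_sweep_produces_seven_masks(self, full_frame_boundary):
        img = make_norm(np.random.default_rng(0).integers(0, 255, (32, 32)))
        masks = sweep_thresholds(img, full_frame_boundary((32, 32)))
        assert sorted(masks) == sorted(DEFAULT_THRESHOLDS) and len(masks) == 7

    def test_zero_threshold_selects_full_interior(self, full_frame_boundary):
        img = make_norm(np.random.default_rng(1).integers(0, 255, (16, 16)))
        mask = sweep_thresholds(img, full_frame_boundary((16, 16)), [0])[0]
        assert mask.all()

    def test_counts_non_increasing_against_pixel_counting(self, full_frame_boundary):
        img = make_norm(np.random.default_rng(2).integers(0, 255, (48, 48)))
        boundary = full_frame_boundary((48, 48))
        masks = sweep_thresholds(img, boundary)
        counts = [int(masks[t].sum()) for t in DEFAULT_THRESHOLDS]
        assert counts == sorted(counts, reverse=True)
        for tau in DEFAULT_THRESHOLDS:
            brute = sum(int(v >= tau) for v in img.pixels.ravel())
            assert int(masks[tau].sum()) == brute

    def test_out_of_range_threshold_rejected(self, full_frame_boundary):
        img = make_norm(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            sweep_thresholds(img, full_frame_boundary((16, 16)), [300])


class TestExtractRegion:
    def test_single_blob_kept_with_zero_excluded(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[5:10, 5:10] = True
        region = extract_region(mask, full_frame_boundary((32, 32)))
        assert region.pixel_count == 25
        assert region.excluded_signal_fraction == 0.0

    def test_largest_of_two_blobs_and_excluded_fraction(self, full_frame_boundary):
        mask = np.zeros((64, 64), bool)
        mask[5:25, 5:30] = True  # 500 px
        mask[40:48, 40:45] = True  # 40 px
        region = extract_region(mask, full_frame_boundary((64, 64)))
        assert region.pixel_count == 500
        assert region.excluded_signal_fraction == pytest.approx(100 * 40 / 540)

    def test_seed_point_overrides_size_policy(self, full_frame_boundary):
        mask = np.zeros((64, 64), bool)
        mask[5:25, 5:30] = True
        mask[40:48, 40:45] = True
        region = extract_region(mask, full_frame_boundary((64, 64)), seed_point=(42, 42))
        assert region.pixel_count == 40

    def test_seed_outside_boundary_rejected(self, full_frame_boundary):
        with pytest.raises(ValueError, match="seed point"):
            extract_region(np.zeros((32, 32), bool), full_frame_boundary((32, 32)), seed_point=(100, 2))

    def test_empty_mask_yields_empty_region(self, full_frame_boundary):
        region = extract_region(np.zeros((32, 32), bool), full_frame_boundary((32, 32)))
        assert region.is_empty and region.centroid_xy is None

    def test_matches_flood_fill_oracle_on_random_masks(self, full_frame_boundary):
        rng = np.random.default_rng(7)
        boundary = full_frame_boundary((32, 32))
        anchor = tuple(boundary.polygon_xy[0])
        for _ in range(50):
            mask = rng.random((32, 32)) < 0.35
            region = extract_region(mask, boundary)
            np.testing.assert_array_equal(region.mask, oracle_largest_component(mask, anchor))

    def test_centroid_is_unweighted_pixel_mean(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[4:8, 10:20] = True
        region = extract_region(mask, full_frame_boundary((32, 32)))
        assert region.centroid_xy == pytest.approx((14.5, 5.5))


class TestAreaPercent:
    def disc_region(self, radius_px, shape):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        c = (shape[0] - 1) / 2
        mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2
        return FluorescenceRegion(mask, 70, int(mask.sum()), (c, c), np.empty((0, 2), int), 0.0)

    def test_disc_in_disc_closed_form(self, full_frame_boundary):
        # 5 mm disc inside a 20 mm eye -> 25%, at 0.05 mm/px within 1%
        scale = 0.05
        shape = (501, 501)
        region = self.disc_region(5.0 / scale, shape)
        boundary = full_frame_boundary(shape, scale)
        boundary.diameter_nt = boundary.diameter_is = 20.0
        assert area_percent(region, boundary, scale) == pytest.approx(25.0, rel=0.01)

    def test_empty_region_is_zero_percent(self, full_frame_boundary):
        region = FluorescenceRegion(np.zeros((32, 32), bool), 70, 0, None, np.empty((0, 2), int), 0.0)
        assert area_percent(region, full_frame_boundary((32, 32)), 0.1) == 0.0

    def test_mask_denominator_flag(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[:16, :] = True
        region = FluorescenceRegion(mask, 70, int(mask.sum()), (0, 0), np.empty((0, 2), int), 0.0)
        boundary = full_frame_boundary((32, 32), 0.1)
        assert area_percent(region, boundary, 0.1, denominator="mask") == pytest.approx(50.0)

    def test_scale_invariance_of_percentage(self, full_frame_boundary):
        region = self.disc_region(10, (64, 64))
        for scale in (0.05, 0.1, 0.2):
            boundary = full_frame_boundary((64, 64), scale)
            expected = 100 * region.pixel_count * scale**2 / boundary.circle_area
            assert area_percent(region, boundary, scale) == pytest.approx(expected)


class TestRadii:
    def region_from_mask(self, mask, boundary):
        return extract_region(mask, boundary, threshold=70)

    def test_feret_rectangle_half_diagonal(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[10:16, 10:18] = True  # 6 x 8 extent -> span 5 x 7 between centers
        region = self.region_from_mask(mask, full_frame_boundary((32, 32)))
        assert radius_feret(region, 1.0) == pytest.approx(math.sqrt(25 + 49) / 2)

    def test_feret_disc_radius(self, full_frame_boundary):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        mask = (rr - 31.5) ** 2 + (cc - 31.5) ** 2 <= 12.0**2
        region = self.region_from_mask(mask, full_frame_boundary((64, 64)))
        assert abs(radius_feret(region, 1.0) - 12.0) <= 0.5

    def test_single_pixel_has_zero_radius(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[4, 4] = True
        region = self.region_from_mask(mask, full_frame_boundary((32, 32)))
        assert radius_feret(region, 1.0) == 0.0
        assert radius_centroid(region, 1.0) == 0.0

    def test_feret_matches_all_pairs_oracle_on_random_blobs(self, full_frame_boundary):
        rng = np.random.default_rng(11)
        boundary = full_frame_boundary((40, 40))
        for _ in range(20):
            mask = np.zeros((40, 40), bool)
            n_seeds = rng.integers(1, 4)
            for _ in range(n_seeds):
                r, c = rng.integers(5, 35, 2)
                h, w = rng.integers(2, 8, 2)
                mask[r : r + h, c : c + w] = True
            region = self.region_from_mask(mask, boundary)
            assert radius_feret(region, 0.7) == pytest.approx(
                all_pairs_feret(region.mask, 0.7), rel=1e-12
            )

    def test_centroid_radius_equals_feret_on_disc_within_half_pixel(self, full_frame_boundary):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        mask = (rr - 31.5) ** 2 + (cc - 31.5) ** 2 <= 14.0**2
        region = self.region_from_mask(mask, full_frame_boundary((64, 64)))
        assert abs(radius_centroid(region, 1.0) - radius_feret(region, 1.0)) <= 0.5

    def test_centroid_radius_crescent_exhaustive_oracle(self, full_frame_boundary):
        rr, cc = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        outer = (rr - 24) ** 2 + (cc - 24) ** 2 <= 18**2
        inner = (rr - 18) ** 2 + (cc - 24) ** 2 <= 14**2
        mask = outer & ~inner
        region = self.region_from_mask(mask, full_frame_boundary((48, 48)))
        cx, cy = region.centroid_xy
        # exhaustive scan over every 4-connected boundary pixel
        best = 0.0
        for r, c in zip(*np.nonzero(mask)):
            neighbors = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            on_edge = any(
                not (0 <= rr2 < 48 and 0 <= cc2 < 48) or not mask[rr2, cc2] for rr2, cc2 in neighbors
            )
            if on_edge:
                best = max(best, math.hypot(c - cx, r - cy))
        assert radius_centroid(region, 1.0) == pytest.approx(best, rel=1e-12)

    def test_loose_geometric_bounds_on_random_blobs(self, full_frame_boundary):
        rng = np.random.default_rng(13)
        boundary = full_frame_boundary((40, 40))
        for _ in range(20):
            mask = np.zeros((40, 40), bool)
            r, c = rng.integers(4, 30, 2)
            h, w = rng.integers(2, 10, 2)
            mask[r : r + h, c : c + w] = True
            region = self.region_from_mask(mask, boundary)
            r_c = radius_centroid(region, 1.0)
            r_f = radius_feret(region, 1.0)
            assert r_c <= 2 * r_f + 1e-12
            assert r_f <= r_c + r_f + 1e-12

    def test_radii_scale_linearly_with_pixel_scale(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[5:20, 8:17] = True
        region = self.region_from_mask(mask, full_frame_boundary((32, 32)))
        assert radius_feret(region, 0.2) == pytest.approx(2 * radius_feret(region, 0.1))
        assert radius_centroid(region, 0.2) == pytest.approx(2 * radius_centroid(region, 0.1))

    def test_empty_region_radius_undefined(self, full_frame_boundary):
        region = extract_region(np.zeros((32, 32), bool), full_frame_boundary((32, 32)))
        with pytest.raises(ValueError, match="undefined"):
            radius_feret(region, 1.0)
        with pytest.raises(ValueError, match="undefined"):
            radius_centroid(region, 1.0)


class TestHemifields:
    def test_all_signal_on_nasal_side(self, full_frame_boundary):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 2:8] = True  # left side; nasal_side="left"
        region = extract_region(mask, full_frame_boundary((32, 32)))
        nasal, temporal = hemifield_fractions(region, full_frame_boundary((32, 32)))
        assert (nasal, temporal) == (100.0, 0.0)

    def test_mirror_symmetric_region_splits_evenly(self, full_frame_boundary):
        mask = np.zeros((33, 33), bool)
        mask[10:20, 10:23] = True  # symmetric about column 16 = boundary centroid
        region = extract_region(mask, full_frame_boundary((33, 33)))
        nasal, temporal = hemifield_fractions(region, full_frame_boundary((33, 33)))
        assert nasal == pytest.approx(50.0)
        assert temporal == pytest.approx(50.0)

    def test_fractions_match_counting_oracle_and_sum_to_100(self, full_frame_boundary):
        rng = np.random.default_rng(5)
        boundary = full_frame_boundary((32, 32))
        mask = rng.random((32, 32)) < 0.3
        region = extract_region(mask, boundary)
        nasal, temporal = hemifield_fractions(region, boundary, nasal_side="left")
        _, cc = np.nonzero(boundary.mask)
        split = cc.mean()
        rr, cols = np.nonzero(region.mask)
        expected_left = (np.sum(cols < split) + 0.5 * np.sum(cols == split)) / len(cols) * 100
        assert nasal == pytest.approx(expected_left)
        assert nasal + temporal == pytest.approx(100.0)
        flipped = hemifield_fractions(region, boundary, nasal_side="right")
        assert flipped == (temporal, nasal)


class TestRepeatabilityAndMeasure:
    def test_deterministic_chain_has_zero_spread(self, demo_eye):
        result = repeatability_audit(demo_eye.normalized, demo_eye.boundary, n_repeats=8)
        assert result.spread_mm == 0.0
        assert result.std_mm == 0.0
        assert len(result.radii_mm) == 8

    def test_two_repeats_identical_inputs_zero_std(self, demo_eye):
        result = repeatability_audit(demo_eye.normalized, demo_eye.boundary, n_repeats=2)
        assert result.std_mm == 0.0

    def test_jitter_spread_matches_rerun_oracle(self, demo_eye):
        from vitreoquant.quantify import extract_region as er, radius_centroid as rc, sweep_thresholds as sw

        result = repeatability_audit(demo_eye.normalized, demo_eye.boundary, n_repeats=6, jitter=True)
        oracle = []
        for i in range(6):
            tau = 70 + ((i % 3) - 1)
            mask = sw(demo_eye.normalized, demo_eye.boundary, [tau])[tau]
            oracle.append(rc(er(mask, demo_eye.boundary, threshold=tau), demo_eye.boundary.pixel_scale))
        assert result.radii_mm == oracle
        assert result.spread_mm == pytest.approx(max(oracle) - min(oracle))

    def test_golden_demo_measurement_reproduced_exactly(self, demo_eye, golden_quant):
        from vitreoquant.quantify import measure_eye

        result = measure_eye(demo_eye.normalized, demo_eye.boundary, metadata=demo_eye.raw.metadata)
        for key, expected in golden_quant.items():
            got = getattr(result, key)
            if isinstance(expected, float):
                assert got == pytest.approx(expected, abs=1e-12), key
            else:
                assert got == expected, key

    def test_empty_fluorescence_flags_radii_undefined(self, full_frame_boundary):
        img = make_norm(np.zeros((64, 64)))
        boundary = full_frame_boundary((64, 64), 0.1)
        result = measure_eye(img, boundary)
        assert result.area_percent == 0.0
        assert result.radius_feret is None and result.radius_centroid is None
        assert result.nasal_fraction is None

    def test_area_monotone_non_increasing_in_threshold(self, demo_eye):
        areas = []
        for tau in DEFAULT_THRESHOLDS:
            res = measure_eye(demo_eye.normalized, demo_eye.boundary, threshold=tau)
            areas.append(res.area_percent)
        assert areas == sorted(areas, reverse=True)


class TestFitDiffusivity:
    def test_exact_line_recovers_slope(self):
        d_true, sigma0_sq, tau = 0.08, 1.0, 70
        times = np.array([4.0, 8.0, 16.0, 24.0])
        r_sq = 2 * math.log(255 / tau) * (sigma0_sq + 2 * d_true * times)
        assert fit_diffusivity(times, np.sqrt(r_sq), threshold=tau) == pytest.approx(d_true)

    def test_requires_two_points_and_valid_threshold(self):
        with pytest.raises(ValueError):
            fit_diffusivity([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_diffusivity([1.0, 2.0], [2.0, 3.0], threshold=0)


def test_boundary_auto_diameters_from_polygon_extents():
    poly = [[10, 20], [90, 20], [90, 80], [10, 80]]
    boundary = EyeBoundary.from_polygon(poly, (100, 100), pixel_scale=0.1)
    assert boundary.diameter_nt == pytest.approx(8.0)
    assert boundary.diameter_is == pytest.approx(6.0)
    assert boundary.mean_diameter == pytest.approx(7.0)
    assert boundary.circle_area == pytest.approx(math.pi * 3.5**2)


def test_self_intersecting_boundary_rejected():
    poly = [[0, 0], [10, 10], [10, 0], [0, 10]]
    with pytest.raises(ValueError, match="simple"):
        EyeBoundary.from_polygon(poly, (32, 32), pixel_scale=0.1)
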