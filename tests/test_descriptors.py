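"""Layered shape descriptors and the full 112-channel trait vector."""

import numpy as np
import pytest

from rootscape import (
    TraitExtractor,
    center_of_mass,
    compute_trait_vector,
    convex_hull_area,
    coord_x_profile,
    crossing_counts,
    default_registry,
    diff_x_profile,
    ellips_profile,
    rect_profile,
    skeletonize,
)
from rootscape.descriptors import TraitRegistry
from rootscape.errors import MeasurementError, ValidationError

from conftest import random_blob_mask, random_point_mask


def gift_wrap_hull_area(points: np.ndarray) -> float:
    """Brute-force oracle: Jarvis march + shoelace, independent of Qhull."""
    pts = np.unique(points, axis=0).astype(float)
    if len(pts) < 3:
        return 0.0
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            if r == p:
                continue
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (
                cross == 0
                and np.linalg.norm(pts[r] - pts[p]) > np.linalg.norm(pts[q] - pts[p])
            ):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):  # degenerate; all collinear
            return 0.0
    if len(hull) < 3:
        return 0.0
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestCenterOfMass:
    def test_filled_square_is_centered(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[17:29, 31:43] = True
        assert center_of_mass(mask) == pytest.approx((0.5, 0.5))

    def test_mass_in_top_row_gives_zero_com_y(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[4, 5:20] = True
        mask[10, 5] = True  # stretch the box downward
        com_x, com_y = center_of_mass(mask)
        assert com_y < 0.1

    def test_single_pixel_reports_half_on_both_axes(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 7] = True
        assert center_of_mass(mask) == (0.5, 0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(MeasurementError):
            center_of_mass(np.zeros((5, 5), dtype=bool))


class TestConvexHull:
    def test_filled_square_hull_of_pixel_centers(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 5:15] = True  # 10x10 pixels -> 9x9 center square
        assert convex_hull_area(mask) == pytest.approx(81.0)

    def test_single_pixel_and_collinear_sets_report_zero(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        assert convex_hull_area(mask) == 0.0
        mask[5, 6:9] = True  # collinear row
        assert convex_hull_area(mask) == 0.0

    def test_matches_gift_wrapping_oracle_on_random_masks(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            mask = random_point_mask(rng)
            expected = gift_wrap_hull_area(np.argwhere(mask))
            assert convex_hull_area(mask) == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestRectProfile:
    def test_uniform_bar_splits_evenly(self):
        mask = np.zeros((50, 20), dtype=bool)
        mask[5:45, 8:12] = True  # 40 rows, divisible by 4
        np.testing.assert_allclose(rect_profile(mask, 4), [0.25] * 4)

    def test_top_quarter_mass_concentrates_in_first_band(self):
        mask = np.zeros((50, 20), dtype=bool)
        mask[5:15, 8:12] = True
        mask[44, 10] = True  # anchor the box bottom
        profile = rect_profile(mask, 4)
        assert profile[0] > 0.97 and profile[1:3].sum() < 0.03

    def test_sums_to_one_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            profile = rect_profile(random_blob_mask(rng), 4)
            assert profile.sum() == pytest.approx(1.0, abs=1e-9)


class TestEllipsProfile:
    def test_final_channel_is_exactly_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            profile = ellips_profile(random_blob_mask(rng), 12)
            assert profile[-1] == 1.0
            assert np.all(np.diff(profile) >= 0)

    def test_single_pixel_mask_saturates_all_rungs(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 5] = True
        np.testing.assert_allclose(ellips_profile(mask, 12), 1.0)


class TestCoordAndDiffX:
    def test_full_width_rectangle(self):
        mask = np.zeros((40, 30), dtype=bool)
        mask[5:35, 4:26] = True
        coord = coord_x_profile(mask, 10)
        np.testing.assert_allclose(coord, 1.0)
        diff = diff_x_profile(coord)
        np.testing.assert_allclose(diff, [1.0] + [0.0] * 9)

    def test_widening_triangle_increases_monotonically(self):
        h, w = 100, 101
        mask = np.zeros((h, w), dtype=bool)
        for r in range(h):
            half = max(1, int(round((0.1 + 0.9 * r / (h - 1)) * (w // 2))))
            mask[r, w // 2 - half : w // 2 + half + 1] = True
        coord = coord_x_profile(mask, 10)
        assert np.all(np.diff(coord) > 0)
        diff = diff_x_profile(coord)
        assert np.all(diff[1:] > 0)

    def test_mask_confined_to_first_band(self):
        mask = np.zeros((50, 40), dtype=bool)
        mask[2:4, 10:20] = True
        mask[48, 15] = True  # extends the box without widening band 0
        coord = coord_x_profile(mask, 10)
        assert coord[0] == pytest.approx(1.0)  # band 0 spans the full bbox width
        assert np.all(coord[1:9] == 0)


class TestCrossingCounts:
    def test_three_disjoint_bars_count_three_everywhere(self):
        mask = np.zeros((60, 40), dtype=bool)
        for c in (5, 18, 31):
            mask[5:55, c : c + 3] = True
        prof = crossing_counts(mask, "horizontal", 30)
        assert prof.mean == 3.0 and prof.max == 3
        np.testing.assert_allclose(prof.layer_means, 3.0)

    def test_single_bar_vertical_axis(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[5:55, 18:21] = True
        prof = crossing_counts(mask, "vertical", 30)
        assert prof.mean == 1.0 and prof.max == 1

    def test_comb_max_equals_tooth_count(self):
        k, spacing = 7, 6
        mask = np.zeros((40, 5 + k * spacing), dtype=bool)
        mask[5, 3 : 3 + k * spacing] = True  # spine
        for t in range(k):
            mask[5:30, 3 + t * spacing] = True
        prof = crossing_counts(mask, "horizontal", 30)
        assert prof.max == k
        # brute-force run counting oracle on the raw rows
        runs = []
        for row in mask[5:30]:
            n, inside = 0, False
            for v in row:
                if v and not inside:
                    n += 1
                inside = bool(v)
            runs.append(n)
        assert max(runs) == k

    def test_mirror_invariance_and_max_dominates_mean(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mask = random_blob_mask(rng)
            a = crossing_counts(mask, "horizontal", 30)
            b = crossing_counts(mask[:, ::-1], "horizontal", 30)
            assert a.mean == pytest.approx(b.mean) and a.max == b.max
            assert a.max >= a.mean

    def test_adding_disjoint_bar_adds_exactly_one_crossing(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            mask = random_blob_mask(rng, (60, 50))
            rows = np.nonzero(mask.any(axis=1))[0]
            wide = np.zeros((60, 60), dtype=bool)
            wide[:, :50] = mask
            wide[rows.min() : rows.max() + 1, 55] = True  # disjoint full-depth bar
            before = crossing_counts(mask, "horizontal", 30)
            after = crossing_counts(wide, "horizontal", 30)
            assert after.mean == pytest.approx(before.mean + 1.0)


class TestTraitVector:
    def test_default_registry_totals(self):
        reg = default_registry()
        assert reg.macro_count == 16
        assert reg.micro_count == 96
        assert reg.channel_count == 112
        assert len(reg.channel_names) == 112
        assert "cross_hori_0_mean" in reg.channel_names
        assert "cross_hori_29_mean" in reg.channel_names

    def test_vector_is_deterministic(self):
        rng = np.random.default_rng(21)
        mask = random_blob_mask(rng)
        v1 = compute_trait_vector(mask)
        v2 = compute_trait_vector(mask)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_graph_from_different_mask_rejected(self):
        rng = np.random.default_rng(22)
        mask_a = random_blob_mask(rng)
        mask_b = ~mask_a
        graph_b = skeletonize(mask_b)
        with pytest.raises(ValidationError):
            compute_trait_vector(mask_a, graph_b)

    def test_registry_round_trips_through_json(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "registry.json"
        reg.to_json(path)
        assert TraitRegistry.from_json(path) == reg

    def test_normalization_invariants_on_random_masks(self):
        reg = default_registry()
        rng = np.random.default_rng(77)
        for _ in range(30):
            vec = compute_trait_vector(random_blob_mask(rng), registry=reg)
            assert vec["rect_layers"].sum() == pytest.approx(1.0, abs=1e-9)
            ellips = vec["ellips_layers"]
            assert np.all(np.diff(ellips) >= 0) and ellips[-1] == 1.0
            assert 0 <= vec["com_x"] <= 1 and 0 <= vec["com_y"] <= 1
            assert np.all((vec["coord_x_layers"] >= 0) & (vec["coord_x_layers"] <= 1))
            assert vec["cross_hori_max"] >= vec["cross_hori_mean"]

    def test_extractor_returns_matrix_in_registry_order(self):
        rng = np.random.default_rng(31)
        masks = [random_blob_mask(rng) for _ in range(3)]
        ext = TraitExtractor()
        out = ext.fit_transform(masks)
        assert out.shape == (3, 112)
        np.testing.assert_array_equal(out[0], compute_trait_vector(masks[0]).values)
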