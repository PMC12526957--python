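"""Background subtraction, pixel features, RF training, mask cleanup."""

import logging

import numpy as np
import pytest

from rootscape import (
    RasterImage,
    RootPixelClassifier,
    clean_mask,
    compute_pixel_features,
    segment,
    subtract_background,
    train_segmenter,
)
from rootscape.errors import ParameterError, TrainingError, ValidationError
from rootscape.segmentation import RootMask, load_model, save_model

from conftest import random_blob_mask


def brute_force_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by explicit shifted min then max over a disc."""
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    pad = radius
    padded = np.pad(img, pad, mode="edge")
    h, w = img.shape
    eroded = np.full_like(img, np.inf)
    for dr, dc in offsets:
        eroded = np.minimum(eroded, padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w])
    padded_e = np.pad(eroded, pad, mode="edge")
    dilated = np.full_like(img, -np.inf)
    for dr, dc in offsets:
        dilated = np.maximum(dilated, padded_e[pad + dr : pad + dr + h, pad + dc : pad + dc + w])
    return dilated


class TestSubtractBackground:
    def test_uniform_image_maps_to_zero(self):
        img = RasterImage(values=np.full((40, 40), 0.4))
        out = subtract_background(img, radius=10)
        assert np.all(out.values == 0.0)

    def test_bright_line_on_ramp_survives_and_background_vanishes(self):
        h, w, radius = 60, 90, 15
        ramp = np.tile(np.linspace(0.0, 0.3, w), (h, 1))
        img = ramp.copy()
        img[:, 40:42] = 0.9
        out = subtract_background(RasterImage(values=img), radius=radius)
        assert out.values[:, 40:42].min() >= 0.55
        off_line = np.ones(w, dtype=bool)
        off_line[36:46] = False
        assert out.values[:, off_line].mean() < 0.02
        # interior agrees with a brute-force opening oracle
        oracle = np.clip(img - brute_force_opening(img, radius), 0.0, 1.0)
        interior = (slice(radius + 1, -radius - 1), slice(radius + 1, -radius - 1))
        np.testing.assert_allclose(out.values[interior], oracle[interior], atol=1e-12)

    def test_dark_roots_polarity_is_inverted(self):
        img = np.full((50, 50), 0.9)
        img[:, 24:26] = 0.1  # dark thin root on bright background
        out = subtract_background(RasterImage(values=img), radius=10)
        assert out.values[:, 24:26].min() > 0.5
        assert out.values[:, :20].max() < 0.05

    def test_radius_zero_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background(RasterImage(values=np.zeros((5, 5))), radius=0)


class TestPixelFeatures:
    def test_plane_count_is_one_plus_four_per_scale(self):
        img = np.random.default_rng(0).random((30, 30))
        assert compute_pixel_features(img, scales=(1, 2)).planes.shape[0] == 9
        assert compute_pixel_features(img, scales=(1, 2, 4)).planes.shape[0] == 13

    def test_constant_image_has_zero_response_planes(self):
        stack = compute_pixel_features(np.full((30, 30), 0.7), scales=(1, 2))
        # all planes except the raw/smoothed intensity are responses
        for plane, name in zip(stack.planes, stack.names):
            if name.startswith(("grad", "ridge", "var")):
                np.testing.assert_allclose(plane, 0.0, atol=1e-10)

    @pytest.mark.parametrize("scales", [(), (-1,), (0,)])
    def test_bad_scales_rejected(self, scales):
        with pytest.raises(ParameterError):
            compute_pixel_features(np.zeros((10, 10)), scales=scales)


def _toy_library(n=5, seed=0, shape=(48, 48)):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        mask = random_blob_mask(rng, shape)
        img = np.where(mask, 0.9, 0.1) + rng.normal(0, 0.02, shape)
        pairs.append((np.clip(img, 0, 1), mask))
    return pairs


class TestTrainSegmenter:
    def test_training_pixels_are_separable(self):
        pairs = _toy_library()
        model = train_segmenter(pairs, scales=(1, 2), trees=30, seed=0)
        tp = fp = fn = 0
        for img, mask in pairs:
            pred = model.predict_mask(img).values
            tp += (pred & mask).sum()
            fp += (pred & ~mask).sum()
            fn += (~pred & mask).sum()
        assert 2 * tp / (2 * tp + fp + fn) >= 0.99

    def test_same_seed_gives_identical_predictions(self):
        pairs = _toy_library()
        probe = _toy_library(n=1, seed=7)[0][0]
        m1 = train_segmenter(pairs, scales=(1, 2), trees=20, seed=3)
        m2 = train_segmenter(pairs, scales=(1, 2), trees=20, seed=3)
        np.testing.assert_array_equal(
            m1.predict_proba_map(probe), m2.predict_proba_map(probe)
        )

    def test_empty_library_rejected(self):
        with pytest.raises(TrainingError):
            train_segmenter([])

    def test_single_class_library_rejected(self):
        img = np.random.default_rng(0).random((20, 20))
        with pytest.raises(TrainingError):
            train_segmenter([(img, np.zeros((20, 20), dtype=bool))])

    def test_model_round_trip_through_file(self, tmp_path):
        pairs = _toy_library(n=3)
        model = train_segmenter(pairs, scales=(1, 2), trees=10, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        probe = pairs[0][0]
        np.testing.assert_array_equal(
            model.predict_proba_map(probe), loaded.predict_proba_map(probe)
        )


class TestSegment:
    def test_otsu_mode_recovers_thin_roots(self):
        from dataclasses import replace

        from conftest import RECOVERY_SPEC
        from rootscape import render_views, simulate_root_system

        spec = replace(RECOVERY_SPEC, seed=5, noise_sigma=0.02, blur_sigma=0.0)
        axes, _ = simulate_root_system(spec)
        view = render_views(axes, spec, angles=(0.0,))[0]
        truth = view.mask.values
        pred = segment(view.image, method="otsu").values
        tp = (pred & truth).sum()
        f1 = 2 * tp / (2 * tp + (pred & ~truth).sum() + (~pred & truth).sum())
        assert f1 >= 0.95

    def test_all_background_returns_empty_mask_with_warning(self, caplog):
        img = RasterImage(values=np.full((30, 30), 0.2))
        with caplog.at_level(logging.WARNING, logger="rootscape.segmentation"):
            mask = segment(img, method="otsu")
        assert mask.is_empty()
        assert any("background" in r.message for r in caplog.records)

    def test_mismatched_feature_config_rejected(self):
        model = train_segmenter(_toy_library(n=2), scales=(1, 2), trees=5, seed=0)
        model.scales = (1.0, 2.0, 4.0)  # tampered config no longer matches
        with pytest.raises(ValidationError):
            segment(np.zeros((20, 20)), method=model)

    def test_output_dimensions_match_input(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            h, w = rng.integers(20, 60, 2)
            img = rng.random((h, w))
            assert segment(RasterImage(values=img), method="otsu").values.shape == (h, w)


class TestCleanMask:
    def test_speckle_removed_large_component_kept(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:30, 5:25] = True  # 500 px
        mask[35, 35:38] = True  # 3 px speckle
        out = clean_mask(mask, min_size=10).values
        assert out[5:30, 5:25].all()
        assert not out[35, 35:38].any()

    def test_ring_becomes_solid_disc_with_fill(self):
        rr, cc = np.ogrid[:21, :21]
        d2 = (rr - 10) ** 2 + (cc - 10) ** 2
        ring = (d2 <= 64) & (d2 > 4)
        out = clean_mask(ring, fill_holes=True).values
        assert out[10, 10]
        assert out.sum() >= (d2 <= 64).sum()

    def test_empty_mask_is_fixed_point(self):
        out = clean_mask(np.zeros((10, 10), dtype=bool), min_size=5, fill_holes=True)
        assert out.is_empty()

    def test_keep_largest_drops_secondary_components(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:20, 2:10] = True
        mask[25:28, 25:28] = True
        out = clean_mask(mask, keep_largest=True).values
        assert out[2:20, 2:10].all() and not out[25:28, 25:28].any()

    def test_idempotence_on_random_masks(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mask = RootMask(values=rng.random((40, 40)) < 0.3)
            once = clean_mask(mask, min_size=8, fill_holes=True, keep_largest=True)
            twice = clean_mask(once, min_size=8, fill_holes=True, keep_largest=True)
            np.testing.assert_array_equal(once.values, twice.values)
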