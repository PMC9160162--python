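"""Detector contract, baseline detector, augmentation, config schema."""

import numpy as np
import pytest

from endoquant import (
    AugmentationSpec,
    BaselineDetector,
    Detection,
    DetectorConfig,
    Mask,
    augment_sample,
    detect_tile,
    match_detections,
    validate_config,
)
from endoquant.detect import DetectorError
from endoquant.synth import SceneSpec, _disk_mask, generate_scene


def toroid_tile(n=10, seed=0, noise_sd=0.0):
    """512-px tile with well-separated rendered toroids + its ground truth."""
    spec = SceneSpec(n_objects=n, seed=seed, noise_sd=noise_sd)
    annotated, _ = generate_scene(spec)
    return annotated.image, annotated.ground_truth


class TestConfigSchema:
    def test_default_config_validates(self):
        assert validate_config(DetectorConfig()) == []

    def test_wrong_anchors_flagged(self):
        bad = DetectorConfig(anchor_sizes=(16, 64, 128, 128))
        assert any("anchor" in v.lower() for v in validate_config(bad))

    def test_wrong_aspect_ratio_flagged(self):
        assert any("aspect" in v for v in validate_config(DetectorConfig(aspect_ratio=2)))

    def test_anchor_fpn_length_mismatch_flagged(self):
        bad = DetectorConfig(anchor_sizes=(32, 64, 128))
        assert any("length" in v for v in validate_config(bad))

    def test_score_threshold_bounds(self):
        assert any("threshold" in v for v in validate_config(DetectorConfig(head_score_threshold=0.0)))


class TestDetectTileContract:
    def test_blank_tile_gives_no_detections(self):
        out = detect_tile(np.zeros((512, 512), dtype=np.uint8), BaselineDetector())
        assert out == []

    def test_ten_separated_toroids_all_found(self):
        tile, gts = toroid_tile(n=10, noise_sd=0.0)
        out = detect_tile(tile, BaselineDetector())
        assert len(out) == 10
        m = match_detections(out, gts)
        assert m.n_tp == 10 and not m.fp and not m.fn

    def test_proposal_cap_keeps_highest_scores(self):
        def flood_detector(tile, config):
            return [
                Detection(
                    Mask(np.ones((2, 2), bool), (2 * (i // 256), 2 * (i % 256))),
                    score=0.5 + i * 1e-4,
                )
                for i in range(1200)
            ]

        out = detect_tile(np.zeros((512, 512), dtype=np.uint8), flood_detector)
        assert len(out) == 1000
        assert min(d.score for d in out) >= 0.5 + 200 * 1e-4

    def test_below_head_threshold_not_emitted(self):
        def low_detector(tile, config):
            return [Detection(Mask(np.ones((2, 2), bool)), score=0.3)]

        assert detect_tile(np.zeros((512, 512), dtype=np.uint8), low_detector) == []

    def test_detector_failure_is_typed_with_tile_id(self):
        def broken(tile, config):
            raise RuntimeError("boom")

        with pytest.raises(DetectorError, match="tile 7"):
            detect_tile(np.zeros((512, 512), dtype=np.uint8), broken, tile_id=7)

    def test_small_tile_padded_and_cropped(self):
        tile, _ = toroid_tile(n=5, noise_sd=0.0)
        out = detect_tile(tile[:480, :480], BaselineDetector())
        for d in out:
            assert d.bbox.row_min < 480 and d.bbox.col_min < 480


class TestBaselineDetector:
    def test_deterministic_bit_exact(self):
        tile, _ = toroid_tile(n=12, seed=3, noise_sd=5.0)
        det = BaselineDetector()
        a = det(tile, DetectorConfig())
        b = det(tile, DetectorConfig())
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.score == y.score
            assert np.array_equal(x.mask.pixels, y.mask.pixels)
            assert x.mask.offset == y.mask.offset

    def test_pure_noise_tile_gives_no_detections(self):
        rng = np.random.default_rng(0)
        tile = np.clip(rng.normal(20, 5, (512, 512)), 0, 255).astype(np.uint8)
        assert BaselineDetector()(tile, DetectorConfig()) == []

    def test_perfect_on_noiseless_nonoverlapping_scene(self):
        tile, gts = toroid_tile(n=25, seed=9, noise_sd=0.0)
        out = detect_tile(tile, BaselineDetector())
        m = match_detections(out, gts)
        n_pred = len(out)
        assert m.n_tp / len(gts) == 1.0  # recall
        assert m.n_tp / n_pred == 1.0  # precision

    def test_overlapping_toroids_split_by_watershed(self):
        # two equal toroids with centers 12 px apart (r = 10): disk overlap
        # ~28% of either area, rendered as one merged bright blob
        from scipy.ndimage import gaussian_filter

        img = np.full((512, 512), 20.0)
        r, inner = 10.0, 5.0
        for cy, cx in [(250.0, 250.0), (250.0, 262.0)]:
            rr, cc = np.meshgrid(
                np.arange(512, dtype=float) + 0.5, np.arange(512, dtype=float) + 0.5, indexing="ij"
            )
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            img[(d2 <= r**2) & (d2 >= inner**2)] = 180.0
        tile = np.clip(np.round(gaussian_filter(img, 1.0)), 0, 255).astype(np.uint8)
        out = detect_tile(tile, BaselineDetector())
        assert len(out) == 2

    def test_scores_in_declared_range(self):
        tile, _ = toroid_tile(n=15, seed=6, noise_sd=5.0)
        for d in BaselineDetector()(tile, DetectorConfig()):
            assert 0.01 <= d.score <= 1.0


class TestAugmentation:
    def test_factors_within_ranges_over_many_draws(self):
        for seed in range(200):
            spec = AugmentationSpec(seed=seed)
            rng = np.random.default_rng(seed)
            b = rng.uniform(*spec.brightness_range)
            c = rng.uniform(*spec.contrast_range)
            s = rng.uniform(*spec.scale_range)
            assert 0.6 <= b <= 1.8 and 0.6 <= c <= 1.8 and 0.5 <= s <= 1.0

    def test_identity_spec_is_identity(self):
        tile, gts = toroid_tile(n=5, noise_sd=0.0)
        spec = AugmentationSpec(
            brightness_range=(1, 1), contrast_range=(1, 1), scale_range=(1, 1),
            horizontal_flip_p=0, vertical_flip_p=0, seed=0,
        )
        img2, masks2 = augment_sample(tile, gts, spec)
        assert np.array_equal(img2, tile)
        assert all(a.global_pixel_set() == b.global_pixel_set() for a, b in zip(masks2, gts))

    def test_double_flip_is_identity_and_isometry_preserves_area(self):
        tile, gts = toroid_tile(n=5, noise_sd=0.0)
        spec = AugmentationSpec(
            brightness_range=(1, 1), contrast_range=(1, 1), scale_range=(1, 1),
            horizontal_flip_p=1.0, vertical_flip_p=0, seed=0,
        )
        img1, m1 = augment_sample(tile, gts, spec)
        assert [m.area for m in m1] == [m.area for m in gts]  # flips are isometries
        img2, m2 = augment_sample(img1, m1, spec)
        assert np.array_equal(img2, tile)
        assert {frozenset(m.global_pixel_set()) for m in m2} == {
            frozenset(m.global_pixel_set()) for m in gts
        }

    def test_geometric_transform_shared_by_image_and_masks(self):
        tile, gts = toroid_tile(n=6, seed=8, noise_sd=0.0)
        spec = AugmentationSpec(seed=13)
        img2, masks2 = augment_sample(tile, gts, spec)
        assert img2.shape == tile.shape
        # bright ring pixels should sit inside/near the transformed masks
        for m in masks2:
            r0, c0 = m.offset
            sub = img2[r0 : r0 + m.pixels.shape[0], c0 : c0 + m.pixels.shape[1]]
            assert sub[m.pixels].mean() > img2.mean()

    def test_deterministic_per_seed(self):
        tile, gts = toroid_tile(n=4, noise_sd=0.0)
        a_img, a_masks = augment_sample(tile, gts, AugmentationSpec(seed=21))
        b_img, b_masks = augment_sample(tile, gts, AugmentationSpec(seed=21))
        assert np.array_equal(a_img, b_img)
        assert [m.global_pixel_set() for m in a_masks] == [m.global_pixel_set() for m in b_masks]

    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(brightness_range=(2.0, 1.0))
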