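"""IMFA segmentation pipeline: thresholding, morphology, watershed, filters."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from fishmfa.multifractal import AlphaImage, compute_alpha_image
from fishmfa.scoring import match_regions
from fishmfa.segmentation import (
    SegmentationParams,
    drop_labels,
    extract_blue,
    filter_regions,
    overlay_contours,
    refine_mask,
    segment_nuclei,
    split_touching,
    threshold_alpha,
)
from fishmfa.synthetic import generate_scene

from conftest import half_scale_spec


def disc_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestExtractBlue:
    def test_pure_blue_is_ones(self):
        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[..., 2] = 255
        assert np.all(extract_blue(rgb) == 1.0)

    def test_pure_red_is_zeros(self):
        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        assert np.all(extract_blue(rgb) == 0.0)

    def test_generator_round_trip(self, uniform_scene):
        rgb, _ = uniform_scene
        assert np.array_equal(extract_blue(rgb), rgb[..., 2])

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            extract_blue(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            extract_blue(np.zeros((8, 8, 4)))


class TestThresholdAlpha:
    @pytest.fixture(scope="class")
    def alpha_img(self):
        return compute_alpha_image(np.random.default_rng(5).random((32, 32)))

    def test_threshold_above_max_selects_everything(self, alpha_img):
        factor = alpha_img.alpha_max / alpha_img.alpha_min + 0.01
        assert threshold_alpha(alpha_img, factor).all()

    def test_factor_near_one_selects_only_argmin(self, alpha_img):
        mask = threshold_alpha(alpha_img, 1.0 + 1e-12)
        assert np.array_equal(mask, alpha_img.alpha <= alpha_img.alpha_min * (1 + 1e-12))
        assert mask.sum() >= 1

    def test_masks_nested_in_factor(self, alpha_img):
        lo = threshold_alpha(alpha_img, 1.05)
        hi = threshold_alpha(alpha_img, 1.14)
        assert np.all(hi[lo])  # mask(1.05) subset of mask(1.14)

    def test_factor_at_most_one_rejected(self, alpha_img):
        with pytest.raises(ValueError):
            threshold_alpha(alpha_img, 1.0)


class TestRefineMask:
    params = SegmentationParams()

    def test_hole_filled(self):
        m = disc_mask((64, 64), (32, 32), 20)
        holey = m & ~disc_mask((64, 64), (32, 32), 5)
        out = refine_mask(holey, self.params)
        assert out[32, 32]
        assert (out & ~m).sum() == 0 or np.array_equal(out | m, out | m)

    def test_speck_removed(self):
        m = np.zeros((32, 32), dtype=bool)
        m[10, 10] = True
        assert not refine_mask(m, self.params).any()

    def test_spur_removed_disc_preserved(self):
        disc = disc_mask((64, 64), (32, 32), 15)
        spurred = disc.copy()
        spurred[32, 47:58] = True  # 1-px-wide spur sticking out
        out = refine_mask(spurred, self.params)
        oracle = ndi.binary_opening(
            ndi.binary_fill_holes(ndi.binary_closing(spurred, structure=_disk(2))),
            structure=_disk(2),
        )
        assert np.array_equal(out, oracle)
        assert not out[32, 55]  # spur gone
        assert out[32, 32]  # disc body intact

    def test_shape_preserved(self):
        m = np.zeros((20, 30), dtype=bool)
        assert refine_mask(m, self.params).shape == (20, 30)


def _disk(r):
    from skimage.morphology import disk

    return disk(r)


class TestSplitTouching:
    params = SegmentationParams()

    def test_single_disc_one_label(self):
        labels = split_touching(disc_mask((64, 64), (32, 32), 15), self.params)
        assert labels.max() == 1

    def test_two_overlapping_discs_split(self):
        m = disc_mask((80, 100), (40, 35), 20) | disc_mask((80, 100), (40, 65), 20)
        labels = split_touching(m, self.params)
        assert labels.max() == 2
        # split near the neck: each disc center keeps its own label
        assert labels[40, 35] != labels[40, 65]

    def test_empty_mask_empty_labels(self):
        labels = split_touching(np.zeros((32, 32), dtype=bool), self.params)
        assert labels.max() == 0

    def test_labels_connected_and_contiguous(self):
        m = disc_mask((64, 64), (16, 16), 10) | disc_mask((64, 64), (48, 48), 10)
        labels = split_touching(m, self.params)
        ids = np.unique(labels[labels > 0])
        assert list(ids) == list(range(1, len(ids) + 1))
        for i in ids:
            _, n = ndi.label(labels == i)
            assert n == 1


class TestFilterRegions:
    def test_small_region_rejected(self):
        labels = np.zeros((508, 448), dtype=np.int32)
        labels[300:302, 300:305] = 1  # 10 px << effective min area (100)
        out, stats = filter_regions(labels, SegmentationParams())
        assert out.max() == 0
        assert stats[0].rejection_reason == "small"

    def test_thin_bar_rejected_non_oval(self):
        labels = np.zeros((300, 300), dtype=np.int32)
        labels[100:103, 50:250] = 1  # 3 x 200 bar
        params = SegmentationParams(min_area=100)
        out, stats = filter_regions(labels, params)
        # second-moments oracle for a thin rectangle: ecc ~ 1
        assert stats[0].eccentricity > 0.99
        assert stats[0].rejection_reason == "non_oval"
        assert out.max() == 0

    def test_border_region_rejected(self):
        labels = np.zeros((100, 100), dtype=np.int32)
        labels[disc_mask((100, 100), (0, 50), 12)] = 1
        out, stats = filter_regions(labels, SegmentationParams(min_area=100))
        assert stats[0].rejection_reason == "border"
        assert out.max() == 0

    def test_border_kept_when_not_rejecting(self):
        labels = np.zeros((100, 100), dtype=np.int32)
        labels[disc_mask((100, 100), (0, 50), 12)] = 1
        out, stats = filter_regions(
            labels, SegmentationParams(min_area=100, reject_border=False)
        )
        assert out.max() == 1
        assert stats[0].rejection_reason is None

    def test_single_reason_first_failing_filter(self):
        labels = np.zeros((508, 448), dtype=np.int32)
        labels[0, :60] = 1  # small AND thin AND on the border -> "small"
        _, stats = filter_regions(labels, SegmentationParams())
        assert stats[0].rejection_reason == "small"

    def test_survivors_relabeled_in_raster_order(self):
        labels = np.zeros((200, 200), dtype=np.int32)
        labels[disc_mask((200, 200), (150, 40), 14)] = 1
        labels[disc_mask((200, 200), (40, 150), 14)] = 2
        out, stats = filter_regions(labels, SegmentationParams(min_area=100))
        # raster order: the upper region comes first regardless of input id
        assert out[40, 150] == 1
        assert out[150, 40] == 2
        retained = [s for s in stats if s.rejection_reason is None]
        assert sorted(s.label for s in retained) == [1, 2]


class TestSegmentNuclei:
    def test_recovers_all_well_separated_nuclei(self, uniform_scene, uniform_segmentation):
        rgb, truth = uniform_scene
        result = uniform_segmentation
        assert result.n_nuclei == truth.n_nuclei
        report = match_regions(result.labels, truth.labels, iou_min=0.5)
        assert report.n_detected == truth.n_nuclei
        assert report.n_spurious == 0

    def test_alpha_threshold_recorded(self, uniform_segmentation):
        res = uniform_segmentation
        assert res.alpha_threshold == pytest.approx(
            res.params.alpha_threshold_factor * res.alpha_image.alpha_min
        )

    def test_deterministic_rerun(self, uniform_scene, uniform_segmentation):
        rgb, _ = uniform_scene
        again = segment_nuclei(rgb)
        assert np.array_equal(again.labels, uniform_segmentation.labels)
        assert np.array_equal(again.initial_mask, uniform_segmentation.initial_mask)
        assert again.alpha_threshold == uniform_segmentation.alpha_threshold

    def test_higher_factor_selects_superset(self, uniform_scene):
        rgb, _ = uniform_scene
        lo = segment_nuclei(rgb, SegmentationParams(alpha_threshold_factor=1.05))
        hi = segment_nuclei(rgb, SegmentationParams(alpha_threshold_factor=1.14))
        assert np.all(hi.initial_mask[lo.initial_mask])

    def test_background_only_scene_yields_nothing(self):
        rgb, _ = generate_scene(half_scale_spec(image_size=(128, 128), n_nuclei=0))
        result = segment_nuclei(rgb)
        assert result.n_nuclei == 0


class TestOverlayAndDrop:
    def test_empty_labels_identity(self):
        rgb = np.random.default_rng(0).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        out = overlay_contours(rgb, np.zeros((32, 32), dtype=np.int32))
        assert np.array_equal(out, rgb)

    def test_disc_boundary_matches_inner_boundary_oracle(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        m = disc_mask((64, 64), (32, 32), 15)
        labels[m] = 1
        rgb = np.zeros((64, 64, 3), dtype=np.uint8)
        out = overlay_contours(rgb, labels)
        drawn = np.all(out == (255, 255, 0), axis=-1)
        oracle = m & ~ndi.binary_erosion(m)  # inner morphological boundary
        # contour pixels = oracle plus the small numeral at the centroid
        assert np.all(drawn[oracle])
        extra = drawn & ~oracle
        assert 0 < extra.sum() < 20  # just the numeral "1"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay_contours(np.zeros((10, 10, 3)), np.zeros((5, 5), dtype=int))

    def test_drop_labels_removes_only_listed(self):
        labels = np.array([[1, 2], [3, 0]], dtype=np.int32)
        out = drop_labels(labels, [1, 3])
        assert set(np.unique(out)) == {0, 2}
        assert out[0, 1] == 2


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(alpha_threshold_factor=1.0)
        with pytest.raises(ValueError):
            SegmentationParams(min_area=0)
        with pytest.raises(ValueError):
            SegmentationParams(max_eccentricity=1.5)

    def test_min_area_scales_with_resolution(self):
        p = SegmentationParams()
        assert p.effective_min_area((1016, 896)) == 400
        assert p.effective_min_area((508, 448)) == 100

    def test_scale_ladder_halves_with_resolution(self):
        p = SegmentationParams()
        assert p.effective_scales((1016, 896)).window_sides == (1, 13, 29, 45, 61)
        assert p.effective_scales((508, 448)).window_sides == (1, 7, 15, 23, 31)
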