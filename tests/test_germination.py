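import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedgerm.counting import SeedComponent
from seedgerm.germination import (
    classify_by_reference,
    count_germinated_by_area,
    detect_radicle_pixels,
    filter_radicle_regions,
    germination_rate,
    seed_size,
    segment_seed,
)
from seedgerm.segmentation import BACKGROUND_OR_RADICLE, SEED_COAT


class TestDetectRadiclePixels:
    def test_cluster_and_channel_floor_both_required(self):
        image = np.array(
            [[[200, 200, 200], [200, 200, 150], [255, 255, 255]]], dtype=np.uint8
        )
        labels = np.array(
            [[BACKGROUND_OR_RADICLE, BACKGROUND_OR_RADICLE, SEED_COAT]]
        )
        mask = detect_radicle_pixels(image, labels, rgb_floor=160)
        assert mask.tolist() == [[True, False, False]]

    def test_floor_is_strict(self):
        image = np.full((1, 1, 3), 160, dtype=np.uint8)
        labels = np.array([[BACKGROUND_OR_RADICLE]])
        assert not detect_radicle_pixels(image, labels, rgb_floor=160).any()


class TestFilterRadicleRegions:
    def test_bounds_remove_extremes(self):
        mask = np.zeros((120, 200), dtype=bool)
        mask[0, :5] = True  # area 5
        mask[10:20, 10:25] = True  # area 150
        mask[40:115, 40:160] = True  # area 9000
        regions = filter_radicle_regions(mask, min_area=20, max_area=2500)
        assert [r.area for r in regions] == [150]

    def test_empty_mask(self):
        assert filter_radicle_regions(np.zeros((5, 5), dtype=bool)) == []

    def test_permissive_bounds_keep_all(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[1:4, 1:4] = True
        mask[10:20, 10:20] = True
        regions = filter_radicle_regions(mask, min_area=1, max_area=np.inf)
        assert [r.area for r in regions] == [9, 100]


class TestGerminationCounting:
    def test_area_threshold_is_strict(self):
        assert count_germinated_by_area([50, 101, 300], tg=100) == 2
        assert count_germinated_by_area([100], tg=100) == 0
        assert count_germinated_by_area([], tg=100) == 0

    @pytest.mark.parametrize(
        "n_r,n_s,expected",
        [(22, 34, 0.6471), (0, 40, 0.0), (29, 36, 0.8056)],
    )
    def test_rates_match_reported_worked_examples(self, n_r, n_s, expected):
        assert germination_rate(n_r, n_s) == pytest.approx(expected, abs=5e-5)

    def test_no_seeds_is_an_error(self):
        with pytest.raises(ValueError, match="no seeds"):
            germination_rate(0, 0)

    @given(st.lists(st.integers(1, 500), max_size=40))
    def test_count_monotone_in_threshold(self, areas):
        counts = [count_germinated_by_area(areas, tg) for tg in (50, 100, 200)]
        assert counts[0] >= counts[1] >= counts[2]


def _segment_with_white_fraction(n_white, n_total=100):
    image = np.zeros((10, 10, 3), dtype=np.uint8)
    flat = image.reshape(-1, 3)
    flat[:n_white] = (255, 255, 255)
    flat[n_white:n_total] = (180, 150, 60)
    mask = np.ones((10, 10), dtype=bool)
    return segment_seed(image, mask, ratio_rgb_floor=100)


class TestSeedSegment:
    def test_area_ratio_from_white_pixel_count(self):
        seg = _segment_with_white_fraction(40)
        assert seg.ratio_whole == pytest.approx(0.4)
        assert seg.radicle_area == 40 and seg.seed_area == 100

    def test_no_white_pixels_ratio_zero(self):
        seg = _segment_with_white_fraction(0)
        assert seg.ratio_whole == 0.0

    def test_all_white_ratio_one(self):
        seg = _segment_with_white_fraction(100)
        assert seg.ratio_whole == 1.0

    @pytest.mark.parametrize("n_white", [10, 37, 80])
    def test_ratio_variants_related_by_identity(self, n_white):
        seg = _segment_with_white_fraction(n_white)
        rb = seg.ratio_body
        assert seg.ratio_whole == pytest.approx(rb / (1 + rb))

    def test_masks_partition_the_seed(self):
        seg = _segment_with_white_fraction(25)
        assert not (seg.radicle_mask & seg.body_mask).any()
        assert np.array_equal(seg.radicle_mask | seg.body_mask, seg.seed_mask)


class TestClassifyByReference:
    @pytest.mark.parametrize(
        "r,r0,expected", [(50, 40, True), (40, 40, True), (10, 40, False)]
    )
    def test_inclusive_threshold(self, r, r0, expected):
        seg = _segment_with_white_fraction(r)
        ref = _segment_with_white_fraction(r0)
        assert classify_by_reference(seg, ref) is expected

    def test_reference_seed_always_germinated(self):
        ref = _segment_with_white_fraction(33)
        assert classify_by_reference(ref, ref)

    @given(st.integers(0, 100), st.integers(1, 100))
    def test_monotone_in_reference_ratio(self, r, r0):
        # raising r0 can only flip germinated -> non-germinated
        seg = _segment_with_white_fraction(r)
        low = classify_by_reference(seg, _segment_with_white_fraction(r0))
        if r0 < 100:
            high = classify_by_reference(seg, _segment_with_white_fraction(r0 + 1) if r0 + 1 <= 100 else _segment_with_white_fraction(100))
            assert low or not high


def _component_from_mask(mask):
    rows, cols = np.nonzero(mask)
    return SeedComponent(
        area=int(mask.sum()),
        bbox=(int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1),
        centroid=(float(rows.mean()), float(cols.mean())),
        mask=mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1],
    )


class TestSeedSize:
    def test_rectangle_matches_covariance_eigendecomposition(self):
        mask = np.zeros((50, 60), dtype=bool)
        mask[5:25, 5:45] = True  # 20 x 40 rectangle
        comp = _component_from_mask(mask)
        length, width = seed_size(comp)
        rows, cols = np.nonzero(mask)
        cov = np.cov(np.stack([rows, cols]))
        eigvals = np.sort(np.linalg.eigvalsh(cov * (len(rows) - 1) / len(rows)))
        assert length == pytest.approx(4 * np.sqrt(eigvals[1]), rel=1e-6)
        assert width == pytest.approx(4 * np.sqrt(eigvals[0]), rel=1e-6)
        assert length >= width

    def test_disk_is_round(self):
        rr, cc = np.mgrid[:41, :41]
        mask = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        length, width = seed_size(_component_from_mask(mask))
        assert width == pytest.approx(length, rel=0.02)

    def test_single_row_degenerate_width(self):
        mask = np.zeros((5, 40), dtype=bool)
        mask[2, 5:35] = True
        with pytest.warns(UserWarning, match="degenerate"):
            length, width = seed_size(_component_from_mask(mask))
        assert width == 0.0
        assert length > 30
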