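import numpy as np
import pytest

from nervequant import (
    BinaryMask,
    Frame,
    RoiPolygon,
    compute_perfusion,
    correct_low_velocity,
    doppler_difference_maps,
    max_project,
    qc_overlay,
    rasterize_roi,
    select_signal,
    simulate_doppler_frame,
    split_rgb,
)
from nervequant.errors import EmptyRegionError, FormatError, ParameterError

from oracles import trace_perfusion

ROI_1000 = RoiPolygon(((0, 0), (40, 0), (40, 25), (0, 25)))


@pytest.fixture(scope="module")
def roi_mask_1000():
    mask = rasterize_roi(ROI_1000, (30, 45))
    assert mask.area_px == 1000
    return mask


def overlay_frame(mask, dark_blue=(40, 30, 200)):
    """Noiseless fixture: 100 cyan + 50 dark-blue px on gray 50 background."""
    px = np.full((30, 45, 3), 50, dtype=np.uint8)
    rows, cols = np.nonzero(mask.pixels)
    px[rows[:100], cols[:100]] = (0, 200, 255)
    px[rows[100:150], cols[100:150]] = dark_blue
    return Frame(px, modality="doppler")


class TestChannelOps:
    def test_split_preserves_intensities(self):
        frame = Frame(np.array([[[10, 20, 30]]], dtype=np.uint8), modality="doppler")
        r, g, b = split_rgb(frame)
        assert (r[0, 0], g[0, 0], b[0, 0]) == (10, 20, 30)

    def test_split_of_gray_triplets_gives_identical_channels(self, rng):
        v = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        r, g, b = split_rgb(Frame(np.stack([v, v, v], -1), modality="doppler"))
        assert np.array_equal(r, g) and np.array_equal(g, b)

    def test_split_rejects_grayscale(self):
        with pytest.raises(FormatError):
            split_rgb(Frame(np.zeros((4, 4), dtype=np.uint8)))

    @pytest.mark.parametrize(
        "pixel, expected",
        [
            ((120, 120, 120), (0, 0, 0, 0)),
            ((0, 200, 255), (200, 55, 0, 0)),
            ((150, 40, 30), (0, 0, 10, 110)),
        ],
    )
    def test_difference_maps_saturating_arithmetic(self, pixel, expected):
        r, g, b = (np.full((1, 1), v, dtype=np.uint8) for v in pixel)
        maps = doppler_difference_maps(r, g, b)
        got = (
            maps.light_blue[0, 0],
            maps.dark_blue[0, 0],
            maps.light_red[0, 0],
            maps.dark_red[0, 0],
        )
        assert got == expected

    def test_max_project_identity_and_idempotence(self, rng):
        a = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        assert np.array_equal(max_project(a, np.zeros_like(a)), a)
        assert np.array_equal(max_project(a, a), a)

    def test_max_project_shape_mismatch(self):
        with pytest.raises(ParameterError):
            max_project(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSelectSignal:
    def test_two_level_map_selects_exactly_the_signal(self, roi_mask_1000):
        m = np.zeros((30, 45), dtype=np.uint8)
        rows, cols = np.nonzero(roi_mask_1000.pixels)
        m[rows[:450], cols[:450]] = 200
        mask, t = select_signal(m, roi_mask_1000)
        assert mask.area_px == 450
        assert t is not None and 0 <= t < 200

    def test_particle_size_filter_removes_small_components(self, roi_mask_1000):
        m = np.zeros((30, 45), dtype=np.uint8)
        rows, cols = np.nonzero(roi_mask_1000.pixels)
        m[rows[:450], cols[:450]] = 200
        mask, _ = select_signal(m, roi_mask_1000, min_particle_px=500)
        assert mask.area_px == 0

    def test_all_zero_map_yields_empty_mask_not_error(self, roi_mask_1000):
        mask, t = select_signal(np.zeros((30, 45), dtype=np.uint8), roi_mask_1000)
        assert mask.area_px == 0 and t is None


class TestLowVelocityCorrection:
    def test_low_equals_high_empties(self):
        m = BinaryMask(np.ones((4, 4), bool))
        assert correct_low_velocity(m, m).area_px == 0

    def test_empty_high_is_identity(self):
        low = BinaryMask(np.eye(4, dtype=bool))
        out = correct_low_velocity(low, BinaryMask(np.zeros((4, 4), bool)))
        assert np.array_equal(out.pixels, low.pixels)

    def test_subset_subtraction(self):
        low = np.zeros((10, 10), bool)
        low.flat[:100] = True  # 100 px
        high = np.zeros((10, 10), bool)
        high.flat[:30] = True  # 30-px subset
        assert correct_low_velocity(BinaryMask(low), BinaryMask(high)).area_px == 70


class TestComputePerfusion:
    def test_grayscale_frame_has_zero_vascular_ratio(self, rng, roi_mask_1000):
        v = rng.integers(0, 256, (30, 45)).astype(np.uint8)
        frame = Frame(np.stack([v, v, v], -1), modality="doppler")
        res = compute_perfusion(frame, roi_mask_1000)
        assert res.vr_percent == 0.0
        assert res.high_velocity_proportion is None
        assert res.degenerate_high and res.degenerate_low

    def test_noiseless_overlay_fixture_matches_stage_oracle(self, roi_mask_1000):
        """Cyan (fast) + non-leaking dark blue (slow): the slow signal is
        corrected by subtracting the fast mask, leaving a 2:1 fast/slow split."""
        frame = overlay_frame(roi_mask_1000, dark_blue=(40, 30, 200))
        res = compute_perfusion(frame, roi_mask_1000)
        assert (res.high_area_px, res.low_corrected_area_px, res.total_area_px) == (100, 50, 150)
        assert res.vr_percent == pytest.approx(15.0)
        assert res.high_velocity_proportion == pytest.approx(2 / 3)
        assert trace_perfusion(frame.pixels, roi_mask_1000.pixels) == (100, 50, 150)

    def test_green_leaking_dark_blue_lands_in_the_fast_mask(self, roi_mask_1000):
        """A dark-blue anchor with G>R leaks G-R=10 into the fast map; the
        entropy criterion then thresholds at 0 and absorbs the slow pixels
        into the fast mask (verified against the independent stage oracle)."""
        frame = overlay_frame(roi_mask_1000, dark_blue=(30, 40, 200))
        res = compute_perfusion(frame, roi_mask_1000)
        oracle = trace_perfusion(frame.pixels, roi_mask_1000.pixels)
        assert (res.high_area_px, res.low_corrected_area_px, res.total_area_px) == oracle == (150, 0, 150)
        assert res.vr_percent == pytest.approx(15.0)
        assert res.high_velocity_proportion == pytest.approx(1.0)

    def test_intensity_domain_correction_agrees_on_disjoint_fixture(self, roi_mask_1000):
        frame = overlay_frame(roi_mask_1000, dark_blue=(40, 30, 200))
        res = compute_perfusion(frame, roi_mask_1000, correct_intensities=True)
        assert res.total_area_px == 150
        assert res.high_area_px == 100

    def test_empty_roi_raises(self):
        frame = Frame(np.zeros((10, 10, 3), np.uint8), modality="doppler")
        with pytest.raises(EmptyRegionError):
            compute_perfusion(frame, BinaryMask(np.zeros((10, 10), bool)))

    def test_partition_high_plus_corrected_low_equals_total(self, octagon_roi, octagon_mask):
        for seed in range(5):
            frame, _ = simulate_doppler_frame(octagon_roi, 0.2, 0.4, seed=seed, shape=(128, 128))
            res = compute_perfusion(frame, octagon_mask)
            assert res.high_area_px + res.low_corrected_area_px == res.total_area_px

    def test_vr_invariant_under_joint_permutation(self, octagon_roi, octagon_mask, rng):
        frame, _ = simulate_doppler_frame(octagon_roi, 0.15, 0.33, seed=2, shape=(128, 128))
        perm_r = rng.permutation(128)
        perm_c = rng.permutation(128)
        shuffled = Frame(frame.pixels[perm_r][:, perm_c], modality="doppler")
        shuffled_mask = BinaryMask(octagon_mask.pixels[perm_r][:, perm_c])
        a = compute_perfusion(frame, octagon_mask)
        b = compute_perfusion(shuffled, shuffled_mask)
        assert a.vr_percent == b.vr_percent
        assert a.high_velocity_proportion == b.high_velocity_proportion

    def test_qc_overlay_tints_masks(self, roi_mask_1000):
        frame = overlay_frame(roi_mask_1000)
        res = compute_perfusion(frame, roi_mask_1000)
        high = BinaryMask(np.zeros((30, 45), bool))
        img = qc_overlay(frame, high, high)
        assert img.shape == (30, 45, 3)
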