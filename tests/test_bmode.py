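import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nervequant import (
    Frame,
    RoiPolygon,
    compute_csa,
    compute_csr,
    compute_fr,
    invert,
    rasterize_roi,
    rolling_ball_background_subtract,
    simulate_bmode_nerve,
)
from nervequant.errors import CalibrationError, EmptyRegionError, ParameterError, ValidationError

SQUARE_100x100 = RoiPolygon(((5, 5), (105, 5), (105, 105), (5, 105)))


def two_level_frame(fascicle_value=30, background_value=200, n_fascicle=3000):
    """Noiseless frame: 10,000-px square ROI, a block of 'fascicle' pixels."""
    img = np.full((128, 128), background_value, dtype=np.uint8)
    mask = rasterize_roi(SQUARE_100x100, (128, 128))
    rows, cols = np.nonzero(mask.pixels)
    img[rows[:n_fascicle], cols[:n_fascicle]] = fascicle_value
    return Frame(img), mask


class TestInvert:
    def test_endpoints(self):
        arr = np.array([[0, 255]], dtype=np.uint8)
        assert invert(arr).tolist() == [[255, 0]]

    @given(st.integers(0, 2**31 - 1))
    def test_involution(self, seed):
        arr = np.random.default_rng(seed).integers(0, 256, (6, 6)).astype(np.uint8)
        assert np.array_equal(invert(invert(arr)), arr)


class TestBackgroundSubtraction:
    def test_uniform_image_goes_to_zero(self):
        out = rolling_ball_background_subtract(np.full((40, 40), 100, np.uint8), 7)
        assert not out.any()

    def test_small_bright_feature_survives(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[20, 20] = 200
        out = rolling_ball_background_subtract(img, 5)
        assert out[20, 20] > 0
        assert out[0, 0] == 0

    def test_output_never_exceeds_input(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert (rolling_ball_background_subtract(img, 4) <= img).all()

    def test_oversized_radius_rejected(self):
        with pytest.raises(ParameterError):
            rolling_ball_background_subtract(np.zeros((10, 10), np.uint8), 11)

    def test_classic_rolling_ball_mode_runs(self):
        img = np.full((20, 20), 50, dtype=np.uint8)
        out = rolling_ball_background_subtract(img, 5, method="rolling_ball")
        assert out.shape == (20, 20)


class TestFascicularRatio:
    def test_noiseless_two_level_frame_recovers_exact_fraction(self):
        frame, _ = two_level_frame()
        res = compute_fr(frame, SQUARE_100x100)
        assert res.fr_percent == pytest.approx(30.0)
        assert res.roi_area_px == 10_000
        assert not res.degenerate

    def test_uniform_roi_reports_zero_with_degenerate_flag(self):
        res = compute_fr(Frame(np.full((128, 128), 77, np.uint8)), SQUARE_100x100)
        assert res.fr_percent == 0.0
        assert res.degenerate and res.threshold_used is None

    def test_empty_roi_is_an_error(self):
        outside = RoiPolygon(((300, 300), (310, 300), (310, 310)))
        with pytest.warns(UserWarning):
            with pytest.raises(EmptyRegionError):
                compute_fr(Frame(np.zeros((128, 128), np.uint8)), outside)

    def test_invariant_to_level_remapping_preserving_separation(self):
        """Any two-level frame with the same geometry gives the same FR."""
        results = set()
        for lo, hi in ((30, 200), (10, 120), (60, 250)):
            frame, _ = two_level_frame(lo, hi)
            results.add(compute_fr(frame, SQUARE_100x100).fr_percent)
        assert results == {30.0}

    def test_processing_order_sensitivity_is_observable(self):
        """Inverting first is load-bearing: if the background is subtracted
        before inversion, dark fascicles belong to the morphological
        background and the signal is flattened away entirely."""
        frame, _ = two_level_frame()
        a = compute_fr(frame, SQUARE_100x100, background_before_invert=False)
        b = compute_fr(frame, SQUARE_100x100, background_before_invert=True)
        assert a.fr_percent == pytest.approx(30.0)
        assert b.degenerate and b.fr_percent == 0.0

    def test_speckled_phantom_recovery_single_condition(self, octagon_roi):
        frame, truth = simulate_bmode_nerve(octagon_roi, 0.5, seed=11, shape=(128, 128))
        res = compute_fr(frame, octagon_roi)
        assert abs(res.fr_percent - 100 * truth.fascicle_fraction) <= 5.0


class TestCsaCsr:
    def test_pixel_count_times_calibration(self):
        res = compute_csa(SQUARE_100x100, (128, 128), 0.004017)
        assert res.roi_area_px == 10_000
        assert res.csa_mm2 == pytest.approx(10_000 * 0.004017)

    def test_forced_product_for_unit_examples(self):
        sq = RoiPolygon(((0, 0), (10, 0), (10, 10), (0, 10)))  # 100 px
        assert compute_csa(sq, (20, 20), 0.004017).csa_mm2 == pytest.approx(0.4017)

    def test_missing_calibration_instructs_flag(self):
        with pytest.raises(CalibrationError, match="pixel-area-mm2"):
            compute_csa(SQUARE_100x100, (128, 128), None)

    @pytest.mark.parametrize(
        "affected, unaffected, expected",
        [([4, 4, 4], [2, 2, 2], 2.0), ([1.5, 2.5], [1.5, 2.5], 1.0), ([3.3], [1.5], 2.2)],
    )
    def test_csr_of_means(self, affected, unaffected, expected):
        assert compute_csr(affected, unaffected) == pytest.approx(expected)

    def test_csr_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            compute_csr([1.0], [0.0])

    def test_csr_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            compute_csr([], [1.0])

    def test_scaled_roi_recovers_area_factor_exactly(self):
        """A side-length x2 polygon has exactly 4x the CSA: CSR = 4.0."""
        small = RoiPolygon(((0, 0), (10, 0), (10, 10), (0, 10)))
        big = RoiPolygon(((0, 0), (20, 0), (20, 20), (0, 20)))
        csa_s = compute_csa(small, (40, 40), 0.004017).csa_mm2
        csa_b = compute_csa(big, (40, 40), 0.004017).csa_mm2
        assert compute_csr([csa_b], [csa_s]) == 4.0
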