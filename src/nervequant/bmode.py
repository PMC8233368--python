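"""B-mode quantification: fascicular ratio (FR), cross-section area (CSA),
and cross-section ratio (CSR).

The fascicular ratio is the percentage of a nerve's cross-section occupied by
hypoechogenic (dark) fascicular tissue. The measurement pipeline on a
transverse B-mode still is:

    8-bit grayscale -> invert -> background subtraction (rolling ball)
    -> ROI histogram -> maximum-entropy threshold -> binarize -> FR

Inversion makes the hypoechogenic fascicles bright so the "above threshold"
convention selects them; background subtraction flattens depth-dependent gain
before thresholding. CSA is the calibrated ROI pixel count; CSR is the ratio
of per-subject mean affected CSA to mean unaffected CSA (an enlargement
factor, ~1 for a healthy nerve).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.morphology import disk, opening
from skimage.restoration import rolling_ball

from .errors import EmptyRegionError, DegenerateHistogramError, CalibrationError, ParameterError, ValidationError
from .io_roi import BinaryMask, Frame, RoiPolygon, rasterize_roi, to_gray_8bit
from .thresholding import apply_threshold, histogram256, max_entropy_threshold

__all__ = [
    "FascicleResult",
    "CsaResult",
    "invert",
    "rolling_ball_background_subtract",
    "compute_fr",
    "compute_csa",
    "compute_csr",
]

#: Default structuring-element radius for background subtraction, in pixels.
DEFAULT_ROLLING_BALL_RADIUS = 50


@dataclass(frozen=True)
class FascicleResult:
    """Outcome of a fascicular-ratio measurement on one frame."""

    hypoechoic_area_px: int
    roi_area_px: int
    fr_percent: float
    threshold_used: int | None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fr_percent <= 100:
            raise ValidationError("fr_percent must lie in [0, 100]")
        if self.hypoechoic_area_px > self.roi_area_px:
            raise ValidationError("foreground cannot exceed ROI area")


@dataclass(frozen=True)
class CsaResult:
    """Calibrated cross-section area of one ROI."""

    roi_area_px: int
    csa_mm2: float


def invert(image: Frame | np.ndarray) -> Frame | np.ndarray:
    """8-bit inversion, v -> 255 - v (an involution)."""
    if isinstance(image, Frame):
        return Frame(255 - image.pixels, pixel_area=image.pixel_area, modality=image.modality)
    return (255 - np.asarray(image, dtype=np.uint8)).astype(np.uint8)


def rolling_ball_background_subtract(
    image: Frame | np.ndarray,
    radius: int = DEFAULT_ROLLING_BALL_RADIUS,
    method: str = "opening",
) -> Frame | np.ndarray:
    """Estimate and subtract a smooth background.

    ``method="opening"`` (default) uses the grayscale morphological opening
    with a disk of the given radius — the flat structuring-element
    approximation of the rolling-ball background; it removes any bright
    feature narrower than the disk from the background estimate. The opening
    is anti-extensive, so the output equals ``clip(image - background, 0,
    255)`` with a non-negative subtrahend. ``method="rolling_ball"`` uses the
    classic parabolic rolling-ball estimate instead.
    """
    arr = image.pixels if isinstance(image, Frame) else np.asarray(image, dtype=np.uint8)
    if arr.ndim != 2:
        raise ParameterError("background subtraction expects a grayscale image")
    radius = int(radius)
    if radius < 1:
        raise ParameterError("rolling-ball radius must be >= 1 px")
    if radius > arr.shape[0] and radius > arr.shape[1]:
        raise ParameterError(
            f"radius {radius} exceeds both image dimensions {arr.shape}"
        )
    if method == "opening":
        footprint = disk(radius, decomposition="sequence")
        background = opening(arr, footprint)
    elif method == "rolling_ball":
        background = rolling_ball(arr, radius=radius)
    else:
        raise ParameterError(f"unknown background method {method!r}")
    out = np.clip(arr.astype(np.int16) - background.astype(np.int16), 0, 255).astype(np.uint8)
    if isinstance(image, Frame):
        return Frame(out, pixel_area=image.pixel_area, modality=image.modality)
    return out


def compute_fr(
    frame: Frame,
    roi: RoiPolygon | BinaryMask,
    radius: int = DEFAULT_ROLLING_BALL_RADIUS,
    background_before_invert: bool = False,
    background_method: str = "opening",
) -> FascicleResult:
    """Fascicular ratio of one B-mode frame within an ROI.

    ``background_before_invert`` flips the order of the inversion and
    background-subtraction steps for sensitivity analysis; the default order
    is invert first. A single-intensity (degenerate) ROI yields FR = 0 with
    the ``degenerate`` flag set so batch runs survive pathological frames;
    an empty ROI is an error.
    """
    gray = to_gray_8bit(frame)
    mask = roi if isinstance(roi, BinaryMask) else rasterize_roi(roi, gray.shape)
    if mask.area_px == 0:
        raise EmptyRegionError("ROI rasterizes to zero pixels")
    if background_before_invert:
        processed = invert(rolling_ball_background_subtract(gray, radius, background_method))
    else:
        processed = rolling_ball_background_subtract(invert(gray), radius, background_method)
    try:
        t = max_entropy_threshold(histogram256(processed, mask))
    except DegenerateHistogramError:
        return FascicleResult(0, mask.area_px, 0.0, None, degenerate=True)
    fg = apply_threshold(processed, t, mask)
    return FascicleResult(
        hypoechoic_area_px=fg.area_px,
        roi_area_px=mask.area_px,
        fr_percent=100.0 * fg.area_px / mask.area_px,
        threshold_used=t,
    )


def compute_csa(
    roi: RoiPolygon,
    shape: tuple[int, int],
    pixel_area: float | None,
) -> CsaResult:
    """Calibrated cross-section area: rasterized ROI pixel count × mm²/px."""
    if pixel_area is None or not pixel_area > 0:
        raise CalibrationError(
            "CSA needs a positive pixel-area calibration; pass pixel_area or "
            "use --pixel-area-mm2"
        )
    mask = rasterize_roi(roi, shape)
    return CsaResult(roi_area_px=mask.area_px, csa_mm2=mask.area_px * pixel_area)


def compute_csr(
    affected_csas: Sequence[float], unaffected_csas: Sequence[float]
) -> float:
    """Cross-section ratio: mean affected CSA over mean unaffected CSA.

    The study design behind this metric averages several frames per side per
    subject; any n >= 1 per side is accepted.
    """
    if len(affected_csas) == 0 or len(unaffected_csas) == 0:
        raise ValidationError("CSR needs at least one CSA per side")
    denom = float(np.mean(unaffected_csas))
    if denom == 0:
        raise ZeroDivisionError("mean unaffected CSA is zero")
    return float(np.mean(affected_csas)) / denom
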