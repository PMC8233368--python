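"""Color-Doppler quantification: vascular ratio (VR), muscle perfusion ratio
(MPR), and the high-velocity flow proportion.

Color-Doppler overlays encode blood flow as a categorical palette on a
grayscale background: blue hues are flow away from the transducer, red hues
toward it, and brightness encodes speed. Channel subtraction turns the RGB
overlay into four class-intensity maps:

    light blue (fast, away)  = G - R
    dark blue  (slow, away)  = B - G
    light red  (fast, toward) = G - B
    dark red   (slow, toward) = R - G

with 8-bit saturating subtraction (negatives clamp to 0), so any pixel with
R = G = B — the whole grayscale background — is exactly zero in all four maps.
Because flow direction is not analyzed, the two fast maps and the two slow
maps are merged by pixel-wise maximum projection. Each merged map is
binarized with the maximum-entropy threshold over the ROI and filtered by
connected-component (particle) size. The slow-velocity mask is corrected by
set-subtracting the fast mask, since palette structure makes fast-flow pixels
bleed into the slow maps. VR (on nerve) or MPR (on muscle; same computation)
is the percentage of ROI pixels in the union of the fast and corrected-slow
masks; the high-velocity proportion is fast area over total area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

from .errors import (
    DegenerateHistogramError,
    EmptyRegionError,
    FormatError,
    ParameterError,
    ValidationError,
)
from .io_roi import BinaryMask, Frame, RoiPolygon, rasterize_roi
from .thresholding import apply_threshold, histogram256, max_entropy_threshold

__all__ = [
    "DopplerMaps",
    "PerfusionResult",
    "split_rgb",
    "doppler_difference_maps",
    "max_project",
    "select_signal",
    "correct_low_velocity",
    "compute_perfusion",
    "qc_overlay",
]


@dataclass(frozen=True)
class DopplerMaps:
    """The four channel-difference intensity maps."""

    light_blue: np.ndarray
    dark_blue: np.ndarray
    light_red: np.ndarray
    dark_red: np.ndarray


@dataclass(frozen=True)
class PerfusionResult:
    """Perfusion quantification of one Doppler frame within an ROI.

    ``vr_percent`` doubles as the MPR when the ROI covers muscle — the
    computation is identical, only the tissue label differs.
    ``high_velocity_proportion`` is ``None`` when no signal was detected.
    """

    roi_area_px: int
    high_area_px: int
    low_corrected_area_px: int
    total_area_px: int
    vr_percent: float
    high_velocity_proportion: float | None
    thresholds_used: dict = field(default_factory=dict)
    degenerate_high: bool = False
    degenerate_low: bool = False

    def __post_init__(self) -> None:
        if self.total_area_px > self.roi_area_px:
            raise ValidationError("signal cannot exceed ROI area")
        if self.high_area_px > self.total_area_px:
            raise ValidationError("fast-flow area cannot exceed total signal area")
        if not 0 <= self.vr_percent <= 100:
            raise ValidationError("vr_percent must lie in [0, 100]")
        if self.high_velocity_proportion is not None and not (
            0 <= self.high_velocity_proportion <= 1
        ):
            raise ValidationError("high_velocity_proportion must lie in [0, 1]")


def split_rgb(frame: Frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB frame into its three channels, bit-exactly."""
    if not frame.is_color:
        raise FormatError("channel split needs an RGB (doppler) frame")
    px = frame.pixels
    return px[..., 0].copy(), px[..., 1].copy(), px[..., 2].copy()


def _sat_sub(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.clip(a.astype(np.int16) - b.astype(np.int16), 0, 255).astype(np.uint8)


def doppler_difference_maps(
    r: np.ndarray, g: np.ndarray, b: np.ndarray
) -> DopplerMaps:
    """Channel-subtraction decomposition into the four velocity/direction maps."""
    if not (r.shape == g.shape == b.shape):
        raise ParameterError("channel shapes differ")
    return DopplerMaps(
        light_blue=_sat_sub(g, r),
        dark_blue=_sat_sub(b, g),
        light_red=_sat_sub(g, b),
        dark_red=_sat_sub(r, g),
    )


def max_project(*maps: np.ndarray) -> np.ndarray:
    """Pixel-wise maximum projection of same-shape intensity maps."""
    if len(maps) < 2:
        raise ParameterError("maximum projection needs at least two maps")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps[1:]):
        raise ParameterError("maps must share a shape")
    return np.maximum.reduce([np.asarray(m) for m in maps])


def select_signal(
    intensity_map: np.ndarray,
    roi_mask: BinaryMask,
    min_particle_px: int = 1,
) -> tuple[BinaryMask, int | None]:
    """Binarize a merged Doppler map within the ROI and size-filter particles.

    Maximum-entropy threshold on the ROI histogram, 8-connected component
    labeling, components of area >= ``min_particle_px`` kept, intersected with
    the ROI. A degenerate ROI histogram (e.g. the map is identically zero —
    absent flow is a valid observation) yields an empty mask and threshold
    ``None``, not an error.
    """
    arr = np.asarray(intensity_map)
    if arr.shape != roi_mask.shape:
        raise ParameterError("map and ROI mask shapes differ")
    try:
        t = max_entropy_threshold(histogram256(arr, roi_mask))
    except DegenerateHistogramError:
        return BinaryMask(np.zeros_like(roi_mask.pixels)), None
    fg = apply_threshold(arr, t, roi_mask).pixels
    if min_particle_px > 1:
        labeled = label(fg, connectivity=2)
        sizes = np.bincount(labeled.ravel())
        keep = sizes >= min_particle_px
        keep[0] = False
        fg = keep[labeled]
    return BinaryMask(fg & roi_mask.pixels), t


def correct_low_velocity(low_mask: BinaryMask, high_mask: BinaryMask) -> BinaryMask:
    """Remove fast-flow bleed-through: the set difference low \\ high."""
    if low_mask.shape != high_mask.shape:
        raise ParameterError("mask shapes differ")
    return BinaryMask(low_mask.pixels & ~high_mask.pixels)


def compute_perfusion(
    frame: Frame,
    roi: RoiPolygon | BinaryMask,
    min_particle_px: int = 1,
    correct_intensities: bool = False,
) -> PerfusionResult:
    """Full perfusion quantification of one color-Doppler frame.

    Pipeline: channel split -> difference maps -> fast map = max(light blue,
    light red), slow map = max(dark blue, dark red) -> signal selection on
    each -> corrected slow = slow \\ fast -> total = fast ∪ corrected slow.

    ``correct_intensities`` switches the slow-velocity correction to the
    intensity domain (saturating slow − fast before thresholding) instead of
    the default mask-domain set difference.
    """
    if not frame.is_color:
        raise FormatError("perfusion quantification needs an RGB (doppler) frame")
    mask = roi if isinstance(roi, BinaryMask) else rasterize_roi(roi, frame.shape)
    if mask.area_px == 0:
        raise EmptyRegionError("ROI rasterizes to zero pixels")
    r, g, b = split_rgb(frame)
    maps = doppler_difference_maps(r, g, b)
    high_map = max_project(maps.light_blue, maps.light_red)
    low_map = max_project(maps.dark_blue, maps.dark_red)
    high, t_high = select_signal(high_map, mask, min_particle_px)
    if correct_intensities:
        low_raw, t_low = select_signal(_sat_sub(low_map, high_map), mask, min_particle_px)
    else:
        low_raw, t_low = select_signal(low_map, mask, min_particle_px)
    low_corr = correct_low_velocity(low_raw, high)
    total = BinaryMask(high.pixels | low_corr.pixels)
    proportion = high.area_px / total.area_px if total.area_px > 0 else None
    return PerfusionResult(
        roi_area_px=mask.area_px,
        high_area_px=high.area_px,
        low_corrected_area_px=low_corr.area_px,
        total_area_px=total.area_px,
        vr_percent=100.0 * total.area_px / mask.area_px,
        high_velocity_proportion=proportion,
        thresholds_used={"high": t_high, "low": t_low},
        degenerate_high=t_high is None,
        degenerate_low=t_low is None,
    )


def qc_overlay(
    frame: Frame, high_mask: BinaryMask, low_corrected_mask: BinaryMask
) -> np.ndarray:
    """RGB audit image: fast-flow mask tinted orange, corrected slow-flow
    mask tinted cyan, on the (grayed) source frame."""
    base = frame.pixels if frame.is_color else np.stack([frame.pixels] * 3, axis=-1)
    out = (base.astype(np.float64) * 0.5).astype(np.uint8)
    out[high_mask.pixels] = (255, 140, 0)
    out[low_corrected_mask.pixels] = (0, 200, 220)
    return out
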